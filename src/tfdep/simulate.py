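"""Synthetic data with recorded ground truth for every pipeline stage.

The generator emulates the statistical structure of an inducible-EMT
factorial experiment: a 2x2 genotype x treatment RNA-seq design (scrambled
control vs cofactor knockdown, each with and without induction of the
transcription factor), ChIP-seq peak sets for the TF and its cofactor with
planted promoter co-binding at dependent genes and preferential TF loss at
co-bound sites after knockdown, and a 10-channel TMT interactome with
planted bait-enriched and condition-rewired proteins.

Counts are negative binomial with a shared dispersion ``a`` parameterised so
that ``var = mu + a * mu**2``.  Every modality draws from its own RNG stream
derived from the master seed, so modalities can be regenerated independently
and outputs are byte-identical for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    GeneSetCollection,
    GenomicInterval,
    PeakSet,
    write_bed,
    write_channel_design,
    write_counts,
    write_design,
    write_gene_models,
    write_gmt,
    write_tmt,
)

__all__ = [
    "ConfigError",
    "GenerationError",
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_counts",
    "simulate_peaks",
    "simulate_tmt",
    "simulate_all",
    "write_simulation",
]

CELLS = (("SCR", "Con"), ("SCR", "Dox"), ("KD", "Con"), ("KD", "Dox"))

# distinct per-modality offsets mixed with the master seed
_STREAM_GENOME, _STREAM_COUNTS, _STREAM_PEAKS, _STREAM_TMT, _STREAM_SETS = range(5)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """The synthetic genome cannot accommodate the requested features."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference condition used throughout the test
    suite: 5,000 genes, 8% planted induction-responsive genes in each
    direction, 10% of induced genes dependent on the cofactor (40 genes),
    all of which carry a co-bound promoter peak.
    """

    n_genes: int = 5000
    n_chroms: int = 5
    chrom_length: int = 100_000_000
    samples_per_cell: int = 3
    nb_dispersion: float = 0.01
    base_mean_log2: float = 8.0
    base_sd_log2: float = 1.0
    frac_up: float = 0.08
    frac_down: float = 0.08
    lfc_up: float = 2.0
    lfc_down: float = -2.0
    frac_dependent: float = 0.10
    attenuation_lfc: float = 1.5
    peak_width: int = 400
    frac_cobound: float = 1.0
    n_background_peaks: int = 2000
    loss_cobound: float = 0.44
    loss_noncobound: float = 0.07
    cofactor_kd_loss: float = 0.80
    tss_exclusion: int = 12_000
    tmt_n_proteins: int = 500
    tmt_n_enriched: int = 30
    tmt_n_rewired: int = 10
    tmt_lfc: float = 2.0
    tmt_rewire_lfc: float = 1.5
    tmt_base_log2: float = 10.0
    tmt_base_sd_log2: float = 1.0
    tmt_noise_sd: float = 0.30
    seed: int = 7

    def __post_init__(self) -> None:
        props = {
            "frac_up": self.frac_up,
            "frac_down": self.frac_down,
            "frac_dependent": self.frac_dependent,
            "frac_cobound": self.frac_cobound,
            "loss_cobound": self.loss_cobound,
            "loss_noncobound": self.loss_noncobound,
            "cofactor_kd_loss": self.cofactor_kd_loss,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigError("frac_up + frac_down must not exceed 1")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.chrom_length <= 20 * self.peak_width:
            raise ConfigError("chrom_length must exceed 20x peak_width")
        if min(self.n_genes, self.n_chroms, self.samples_per_cell) < 1:
            raise ConfigError("counts must be positive")
        if self.tmt_n_enriched > self.tmt_n_proteins:
            raise ConfigError("tmt_n_enriched exceeds tmt_n_proteins")
        if self.tmt_n_rewired > self.tmt_n_enriched:
            raise ConfigError("tmt_n_rewired exceeds tmt_n_enriched")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one data modality."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted truth recorded alongside the synthetic data.

    ``genes`` has one row per gene: planted category (up/down/null), the
    dependence flag, whether a co-bound promoter peak was planted, and the
    planted log2 fold change in each contrast.  ``peaks`` and ``proteins``
    are filled in by :func:`simulate_peaks` / :func:`simulate_tmt`.
    """

    genes: pd.DataFrame
    gene_models: list[GeneModel] = field(default_factory=list)
    peaks: pd.DataFrame | None = None
    proteins: pd.DataFrame | None = None

    @property
    def planted_up(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["category"] == "up", "gene_id"])

    @property
    def planted_down(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["category"] == "down", "gene_id"])

    @property
    def planted_dependent(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["dependent"], "gene_id"])

    @property
    def planted_cobound(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["cobound"], "gene_id"])


# ---------------------------------------------------------------------------
# genome and expression
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Place gene TSSs on synthetic chromosomes ``chrS1..chrSn``.

    Genes are spread evenly with deterministic jitter, keeping a margin at
    both chromosome ends so promoter peaks never run off the sequence.
    """
    rng = config.rng(_STREAM_GENOME)
    per_chrom = _split_evenly(config.n_genes, config.n_chroms)
    width = len(str(config.n_genes))
    models: list[GeneModel] = []
    gene_no = 0
    margin = config.tss_exclusion + config.peak_width
    for c, n_here in enumerate(per_chrom, start=1):
        if n_here == 0:
            continue
        usable = config.chrom_length - 2 * margin
        spacing = usable // (n_here + 1)
        if spacing <= 4 * config.peak_width:
            raise GenerationError(
                "chromosome too short for the requested gene density"
            )
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=n_here)
        strands = rng.choice(np.array(["+", "-"]), size=n_here)
        for i in range(n_here):
            tss = margin + (i + 1) * spacing + int(jitter[i])
            models.append(
                GeneModel(f"g{gene_no:0{width}d}", f"chrS{c}", str(strands[i]), tss)
            )
            gene_no += 1
    return models


def _split_evenly(total: int, bins: int) -> list[int]:
    base, rem = divmod(total, bins)
    return [base + (1 if i < rem else 0) for i in range(bins)]


def _plant_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign planted categories, dependence and per-contrast fold changes."""
    n = config.n_genes
    width = len(str(n))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(n)])
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    perm = rng.permutation(n)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]
    category = np.full(n, "null", dtype=object)
    category[up_idx] = "up"
    category[down_idx] = "down"

    n_dep = int(round(config.frac_dependent * n_up))
    dep_idx = up_idx[: n_dep] if n_dep else up_idx[:0]
    dependent = np.zeros(n, dtype=bool)
    dependent[dep_idx] = True

    n_cb = int(round(config.frac_cobound * n_dep))
    cobound = np.zeros(n, dtype=bool)
    cobound[dep_idx[:n_cb]] = True

    lfc_scr = np.zeros(n)
    lfc_scr[up_idx] = config.lfc_up
    lfc_scr[down_idx] = config.lfc_down
    lfc_kd = lfc_scr.copy()
    lfc_kd[dep_idx] = config.lfc_up - config.attenuation_lfc

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": category,
            "dependent": dependent,
            "cobound": cobound,
            "lfc_scr": lfc_scr,
            "lfc_kd": lfc_kd,
        }
    )


def nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial sample with ``var = mu + dispersion * mu**2``.

    Implemented as a gamma-Poisson mixture; ``dispersion = 0`` degenerates
    to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the 2x2 factorial count matrix.

    Returns ``(counts, design, truth)``: a gene x sample integer matrix, the
    sample design covering SCR-Con / SCR+Dox / KD-Con / KD+Dox, and the
    recorded ground truth (which also carries the synthetic gene models so
    peaks can be placed on the same genome).

    Per-gene means are ``2**(baseline + planted lfc)`` scaled by a
    per-sample library-size factor drawn log-uniform in [0.7, 1.4].
    """
    rng = config.rng(_STREAM_COUNTS)
    genes = _plant_genes(config, rng)
    models = simulate_genome(config)

    n = config.n_genes
    baseline = rng.normal(config.base_mean_log2, config.base_sd_log2, size=n)

    sample_ids: list[str] = []
    rows = []
    for genotype, treatment in CELLS:
        for r in range(1, config.samples_per_cell + 1):
            sample_ids.append(f"{genotype}_{treatment}_{r}")
            rows.append((sample_ids[-1], genotype, treatment, r))
    design = pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "replicate"])

    size_factors = np.exp2(rng.uniform(np.log2(0.7), np.log2(1.4), size=len(sample_ids)))

    lfc_scr = genes["lfc_scr"].to_numpy()
    lfc_kd = genes["lfc_kd"].to_numpy()
    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, (_, genotype, treatment, _) in enumerate(rows):
        effect = np.zeros(n)
        if treatment == "Dox":
            effect = lfc_scr if genotype == "SCR" else lfc_kd
        mu = np.exp2(baseline + effect) * size_factors[j]
        counts[:, j] = nb_draw(rng, mu, config.nb_dispersion)

    matrix = pd.DataFrame(counts, index=pd.Index(genes["gene_id"], name="gene_id"),
                          columns=sample_ids)
    truth = GroundTruth(genes=genes, gene_models=models)
    return matrix, design, truth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def simulate_peaks(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, dict[str, PeakSet]]:
    """Simulate TF and cofactor peak sets for both genotypes.

    Factors are ``"tf"`` (the induced transcription factor) and
    ``"cofactor"``; conditions are ``"scr"`` (control genotype, induced) and
    ``"kd"`` (cofactor knockdown, induced).  Planted co-bound genes receive
    overlapping TF and cofactor peaks at their promoter in ``scr``; in
    ``kd`` the TF loses co-bound peaks at rate ``loss_cobound`` and
    background peaks at rate ``loss_noncobound``, and most cofactor peaks
    disappear.  Background peaks sit on a fixed-pitch grid at least
    ``tss_exclusion`` bp from every TSS, guaranteeing >=1 peak-width gaps.

    Fills ``truth.peaks`` and returns ``{factor: {condition: PeakSet}}``.
    """
    if not truth.gene_models:
        raise GenerationError("gene models must be placed before peaks")
    rng = config.rng(_STREAM_PEAKS)
    w = config.peak_width
    half = w // 2

    tss_by_chrom: dict[str, list[int]] = {}
    for m in truth.gene_models:
        tss_by_chrom.setdefault(m.chrom, []).append(m.tss)

    # planted promoter peaks at co-bound genes, TF offset so the pair
    # overlaps without being identical
    gene_rows = truth.genes.set_index("gene_id")
    records: list[dict] = []
    tf_scr: list[GenomicInterval] = []
    cof_scr: list[GenomicInterval] = []
    cobound_flags: list[bool] = []
    model_by_id = {m.gene_id: m for m in truth.gene_models}
    for gid in sorted(truth.planted_cobound):
        m = model_by_id[gid]
        cof_iv = GenomicInterval(m.chrom, m.tss - half, m.tss - half + w,
                                 f"cof_{gid}")
        tf_start = m.tss - half + w // 4
        tf_iv = GenomicInterval(m.chrom, tf_start, tf_start + w, f"tf_{gid}")
        cof_scr.append(cof_iv)
        tf_scr.append(tf_iv)
        cobound_flags.append(True)
        records.append({"name": tf_iv.name, "factor": "tf", "chrom": m.chrom,
                        "start": tf_iv.start, "end": tf_iv.end,
                        "cobound": True, "target_gene": gid})
        records.append({"name": cof_iv.name, "factor": "cofactor",
                        "chrom": m.chrom, "start": cof_iv.start,
                        "end": cof_iv.end, "cobound": True, "target_gene": gid})

    # background peaks per factor on a shared slot grid away from TSSs
    slots = _background_slots(config, tss_by_chrom)
    for factor, bucket in (("tf", tf_scr), ("cofactor", cof_scr)):
        if config.n_background_peaks > len(slots):
            raise GenerationError(
                f"genome too small: {config.n_background_peaks} background "
                f"peaks requested, {len(slots)} slots available"
            )
        chosen = rng.choice(len(slots), size=config.n_background_peaks, replace=False)
        for k, slot_idx in enumerate(sorted(chosen)):
            chrom, pos = slots[slot_idx]
            iv = GenomicInterval(chrom, pos, pos + w, f"{factor}_bg{k}")
            bucket.append(iv)
            if factor == "tf":
                cobound_flags.append(False)
            records.append({"name": iv.name, "factor": factor, "chrom": chrom,
                            "start": iv.start, "end": iv.end,
                            "cobound": False, "target_gene": TSV_NA_GENE})

    # knockdown condition: drop TF peaks preferentially at co-bound sites
    cb = np.asarray(cobound_flags)
    loss_p = np.where(cb, config.loss_cobound, config.loss_noncobound)
    tf_lost = rng.random(len(tf_scr)) < loss_p
    tf_kd = [iv for iv, lost in zip(tf_scr, tf_lost) if not lost]
    cof_lost = rng.random(len(cof_scr)) < config.cofactor_kd_loss
    cof_kd = [iv for iv, lost in zip(cof_scr, cof_lost) if not lost]

    lost_by_name = {iv.name: bool(lost) for iv, lost in zip(tf_scr, tf_lost)}
    lost_by_name.update({iv.name: bool(lost) for iv, lost in zip(cof_scr, cof_lost)})
    peaks_df = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["name", "factor", "chrom", "start", "end", "cobound", "target_gene"]
    )
    if len(peaks_df):
        peaks_df["lost_in_kd"] = peaks_df["name"].map(lost_by_name)
    else:
        peaks_df["lost_in_kd"] = pd.Series(dtype=bool)
    truth.peaks = peaks_df

    return {
        "tf": {"scr": PeakSet(tf_scr), "kd": PeakSet(tf_kd)},
        "cofactor": {"scr": PeakSet(cof_scr), "kd": PeakSet(cof_kd)},
    }


TSV_NA_GENE = "."


def _background_slots(
    config: SimulationConfig, tss_by_chrom: Mapping[str, list[int]]
) -> list[tuple[str, int]]:
    """Fixed-pitch candidate start positions away from every TSS.

    Pitch is 2x peak width so distinct slots never leave less than one
    peak-width of clearance.
    """
    pitch = 2 * config.peak_width
    slots: list[tuple[str, int]] = []
    for c in range(1, config.n_chroms + 1):
        chrom = f"chrS{c}"
        tss = np.asarray(sorted(tss_by_chrom.get(chrom, [])), dtype=np.int64)
        starts = np.arange(config.peak_width, config.chrom_length - 2 * config.peak_width, pitch)
        if len(tss):
            mid = starts + config.peak_width // 2
            j = np.searchsorted(tss, mid)
            left = np.where(j > 0, mid - tss[np.maximum(j - 1, 0)], np.iinfo(np.int64).max)
            right = np.where(j < len(tss), tss[np.minimum(j, len(tss) - 1)] - mid,
                             np.iinfo(np.int64).max)
            keep = np.minimum(left, right) > config.tss_exclusion
            starts = starts[keep]
        slots.extend((chrom, int(s)) for s in starts)
    return slots


# ---------------------------------------------------------------------------
# TMT interactome
# ---------------------------------------------------------------------------


def simulate_tmt(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the 10-channel TMT pull-down (3+3 bait, 2+2 IgG).

    Intensities are log-normal.  Planted-enriched proteins are elevated by
    ``tmt_lfc`` (log2) in bait channels over IgG; a ``tmt_n_rewired`` subset
    is additionally shifted by ``tmt_rewire_lfc`` in the induced-condition
    bait channels.  Each channel is multiplied by a known scaling factor
    (log-uniform [0.7, 1.4]) so normalization has real work to do.
    """
    rng = config.rng(_STREAM_TMT)
    n = config.tmt_n_proteins
    width = len(str(n))
    protein_ids = np.array([f"P{i:0{width}d}" for i in range(n)])

    enriched = np.zeros(n, dtype=bool)
    enriched[: config.tmt_n_enriched] = True
    rewired = np.zeros(n, dtype=bool)
    rewired[: config.tmt_n_rewired] = True
    perm = rng.permutation(n)
    enriched = enriched[perm]
    rewired = rewired[perm]
    if config.tmt_lfc == 0:
        enriched[:] = False
        rewired[:] = False

    channels = []
    for cond in ("Con", "Dox"):
        for r in (1, 2, 3):
            channels.append((f"bait_{cond}_{r}", "bait", cond, r))
    for cond in ("Con", "Dox"):
        for r in (1, 2):
            channels.append((f"IgG_{cond}_{r}", "IgG", cond, r))
    design = pd.DataFrame(channels, columns=["channel_id", "pulldown", "condition", "replicate"])

    base = rng.normal(config.tmt_base_log2, config.tmt_base_sd_log2, size=n)
    scale = np.exp2(rng.uniform(np.log2(0.7), np.log2(1.4), size=len(channels)))

    log2 = np.empty((n, len(channels)))
    for j, (_, pulldown, cond, _) in enumerate(channels):
        mu = base.copy()
        if pulldown == "bait":
            mu = mu + np.where(enriched, config.tmt_lfc, 0.0)
            if cond == "Dox":
                mu = mu + np.where(rewired, config.tmt_rewire_lfc, 0.0)
        log2[:, j] = mu + rng.normal(0.0, config.tmt_noise_sd, size=n)
    intensities = np.exp2(log2) * scale

    matrix = pd.DataFrame(intensities,
                          index=pd.Index(protein_ids, name="protein_id"),
                          columns=[c[0] for c in channels])
    proteins = pd.DataFrame(
        {"protein_id": protein_ids, "enriched": enriched, "rewired": rewired}
    )
    if truth is None:
        truth = GroundTruth(genes=pd.DataFrame(
            columns=["gene_id", "category", "dependent", "cobound", "lfc_scr", "lfc_kd"]
        ))
    truth.proteins = proteins
    return matrix, design, truth


# ---------------------------------------------------------------------------
# gene sets and full bundle
# ---------------------------------------------------------------------------


def planted_gene_sets(
    config: SimulationConfig, truth: GroundTruth, n_random: int = 3, random_size: int = 50
) -> GeneSetCollection:
    """GMT-style collection: the planted categories plus random decoy sets."""
    rng = config.rng(_STREAM_SETS)
    all_genes = list(truth.genes["gene_id"])
    sets: dict[str, list[str]] = {}
    if truth.planted_up:
        sets["PLANTED_UP"] = sorted(truth.planted_up)
    if truth.planted_down:
        sets["PLANTED_DOWN"] = sorted(truth.planted_down)
    if truth.planted_dependent:
        sets["PLANTED_DEPENDENT"] = sorted(truth.planted_dependent)
    for k in range(1, n_random + 1):
        pick = rng.choice(len(all_genes), size=min(random_size, len(all_genes)),
                          replace=False)
        sets[f"RANDOM_{k}"] = sorted(all_genes[i] for i in pick)
    return GeneSetCollection(sets, universe=all_genes)


def simulate_all(config: SimulationConfig):
    """Run all three generators on one config; returns a dict bundle."""
    counts, design, truth = simulate_counts(config)
    peaks = simulate_peaks(config, truth)
    tmt, channels, truth = simulate_tmt(config, truth)
    gene_sets = planted_gene_sets(config, truth)
    return {
        "counts": counts,
        "design": design,
        "peaks": peaks,
        "tmt": tmt,
        "channels": channels,
        "gene_sets": gene_sets,
        "truth": truth,
    }


def write_simulation(bundle: dict, outdir: str | Path) -> None:
    """Write every synthetic artifact as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(bundle["counts"], out / "counts.tsv")
    write_design(bundle["design"], out / "design.tsv")
    truth: GroundTruth = bundle["truth"]
    write_gene_models(truth.gene_models, out / "gene_models.tsv")
    for factor, conds in bundle["peaks"].items():
        for cond, ps in conds.items():
            write_bed(ps, out / f"peaks_{factor}_{cond}.bed")
    write_gmt(bundle["gene_sets"], out / "gene_sets.gmt")
    write_tmt(bundle["tmt"], out / "tmt.tsv")
    write_channel_design(bundle["channels"], out / "channel_design.tsv")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    if truth.peaks is not None:
        truth.peaks.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
    if truth.proteins is not None:
        truth.proteins.to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
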