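"""Seeded synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here with the
latent truth returned alongside, so recovery can be tested end to end:

* a tumor cohort with cluster-structured relative exon-usage profiles and
  cluster-dependent exponential survival hazards (the shape of a TCGA-style
  exon-quantification + clinical download);
* spectral-count tables with Poisson prey counts and fixed bait counts;
* phosphopeptide intensity quartets with latent ionization efficiencies,
  per-run spray scale factors, and known per-phase occupancies;
* read alignments over BED exons for the RPKM path.

All generators take a single integer seed and are deterministic: the same
spec yields byte-identical output.

Usage-profile consistency: a relative-usage vector (u_i = 100 r_i /
(S - r_i)) has one fewer degree of freedom than its length, so not every
positive vector is realizable from an RPKM composition. Cluster profiles
are therefore mapped to the composition simplex via w_i ~ u_i/(100 + u_i)
(normalized); a profile built with :func:`usage_profile` is exactly
self-consistent, and then zero noise reproduces it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exonquant import ExonDef, ExonUsageMatrix, relative_usage, usage_matrix_from_rpkm
from .ipstats import SpectralCountTable
from .phospho import PhosphoIntensityQuartet

__all__ = [
    "CohortSpec",
    "IpmsSpec",
    "PhosphoSpec",
    "usage_profile",
    "default_cluster_profiles",
    "gen_exon_cohort",
    "gen_ipms_counts",
    "gen_phospho_intensities",
    "gen_read_alignments",
    "write_exon_quant",
    "write_clinical",
    "write_bed",
    "write_count_table",
    "write_phospho_csv",
]


def usage_profile(weights: Sequence[float]) -> np.ndarray:
    """Self-consistent relative-usage profile (percent) from abundance weights.

    ``weights`` are relative per-exon RPKM abundances; the returned vector
    is exactly the usage a patient with that RPKM composition would show.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return relative_usage(w)


def default_cluster_profiles(n_exons: int = 37) -> list[np.ndarray]:
    """Three 37-exon usage profiles emulating the reported cohort structure.

    Cluster 0: elevated 5' exons (2-11), depleted 3' exons (30-37) — the
    poor-survival pattern. Cluster 1: flat, MCF10A-like intermediate.
    Cluster 2: the mirror image, best survival.
    """
    if n_exons < 12:
        raise ValueError("default profiles need >= 12 exons")
    flat = np.ones(n_exons)
    hi5 = flat.copy()
    hi5[1:11] = 2.5
    hi5[29:] = 0.4
    hi3 = flat.copy()
    hi3[1:11] = 0.4
    hi3[29:] = 2.5
    return [usage_profile(hi5), usage_profile(flat), usage_profile(hi3)]


@dataclass
class CohortSpec:
    """Design of a synthetic survival cohort.

    Hazards are exponential event rates in events/day; censoring is an
    independent uniform censor time on [min_followup, 3 x overall median
    survival], applied to each patient with probability ``censor_rate``.
    """

    n_patients: int = 600
    n_exons: int = 37
    cluster_profiles: Sequence[np.ndarray] | None = None
    cluster_sizes: Sequence[int] | None = None
    usage_noise_sd: float = 1.5
    hazards: Sequence[float] = (5e-4, 2e-4, 1e-4)
    censor_rate: float = 0.7
    min_followup: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("n_exons must be >= 2")
        if self.cluster_profiles is None:
            self.cluster_profiles = default_cluster_profiles(self.n_exons)
        self.cluster_profiles = [np.asarray(p, dtype=float) for p in self.cluster_profiles]
        k = len(self.cluster_profiles)
        if k != len(self.hazards):
            raise ValueError("one hazard per cluster required")
        if self.cluster_sizes is None:
            base = self.n_patients // k
            sizes = [base] * k
            sizes[0] += self.n_patients - base * k
            self.cluster_sizes = sizes
        if sum(self.cluster_sizes) != self.n_patients:
            raise ValueError("cluster_sizes must sum to n_patients")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("empty clusters not allowed")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be > 0")
        for p in self.cluster_profiles:
            if p.shape != (self.n_exons,) or np.any(p < 0):
                raise ValueError("profiles must be non-negative vectors of length n_exons")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.usage_noise_sd < 0:
            raise ValueError("usage_noise_sd must be >= 0")


# marginal receptor-status frequencies, roughly breast-cohort-like
_ER_LEVELS = (("pos", 0.72), ("neg", 0.21), ("unavailable", 0.07))
_HER2_LEVELS = (("pos", 0.30), ("neg", 0.43), ("equivocal", 0.14), ("unavailable", 0.13))


def _draw_status(rng: np.random.Generator, levels, n: int) -> np.ndarray:
    names = [x[0] for x in levels]
    probs = np.array([x[1] for x in levels])
    return rng.choice(names, size=n, p=probs / probs.sum())


def gen_exon_cohort(
    spec: CohortSpec,
) -> tuple[ExonUsageMatrix, pd.DataFrame, np.ndarray]:
    """Generate a cohort: usage matrix, clinical table, true cluster labels.

    Per patient: the cluster profile gets Gaussian noise (sd in percentage
    points, truncated at 0) in usage space, is mapped back to an RPKM
    composition, and scaled by a log-normal library factor. Event times are
    exponential with the cluster hazard; censored patients report
    days_to_last_followup instead of days_to_death.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(np.arange(len(spec.cluster_sizes)), spec.cluster_sizes)

    # usage-space noise, then back onto the composition simplex
    profiles = np.vstack([spec.cluster_profiles[g] for g in labels])
    noisy = profiles + rng.normal(0.0, spec.usage_noise_sd, size=profiles.shape)
    noisy = np.maximum(noisy, 0.0)
    comp = noisy / (100.0 + noisy)
    comp_sum = comp.sum(axis=1, keepdims=True)
    comp_sum[comp_sum == 0] = 1.0
    comp = comp / comp_sum
    library_scale = rng.lognormal(mean=np.log(50.0), sigma=0.4, size=(spec.n_patients, 1))
    rpkm_values = comp * library_scale

    barcodes = [f"SYN-{i:04d}" for i in range(spec.n_patients)]
    exon_ids = list(range(1, spec.n_exons + 1))
    rpkm = pd.DataFrame(rpkm_values, index=pd.Index(barcodes, name="barcode"), columns=exon_ids)
    usage = usage_matrix_from_rpkm(rpkm)

    hazards = np.asarray(spec.hazards, dtype=float)[labels]
    event_time = rng.exponential(1.0 / hazards)
    overall_median = float(np.log(2) / np.median(hazards))
    censor_hi = max(3.0 * overall_median, spec.min_followup + 1.0)
    censor_time = rng.uniform(spec.min_followup, censor_hi, size=spec.n_patients)
    is_censoring_subject = rng.random(spec.n_patients) < spec.censor_rate
    observed = np.where(
        is_censoring_subject, np.minimum(event_time, censor_time), event_time
    )
    event = ~(is_censoring_subject & (censor_time < event_time))

    clinical = pd.DataFrame(
        {
            "barcode": barcodes,
            "vital_status": np.where(event, "Dead", "Alive"),
            "days_to_death": np.where(event, np.round(observed, 1), np.nan),
            "days_to_last_followup": np.where(event, np.nan, np.round(observed, 1)),
            "er_status": _draw_status(rng, _ER_LEVELS, spec.n_patients),
            "her2_status": _draw_status(rng, _HER2_LEVELS, spec.n_patients),
        }
    )
    return usage, clinical, labels


@dataclass
class IpmsSpec:
    """Poisson spectral-count model: fixed bait counts, per-prey rates."""

    bait_counts: Mapping[str, int]
    prey_rates: Mapping[str, Mapping[str, float]]
    bait_name: str = "BAIT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bait_counts:
            raise ValueError("at least one condition required")
        if any(c <= 0 for c in self.bait_counts.values()):
            raise ValueError("bait counts must be > 0")
        for prey, rates in self.prey_rates.items():
            if set(rates) != set(self.bait_counts):
                raise ValueError(f"prey {prey!r} does not cover all conditions")
            if any(r < 0 for r in rates.values()):
                raise ValueError(f"negative rate for prey {prey!r}")


def gen_ipms_counts(spec: IpmsSpec) -> SpectralCountTable:
    """Draw prey counts Poisson(rate) per condition; bait counts pass through."""
    rng = np.random.default_rng(spec.seed)
    conditions = list(spec.bait_counts)
    rows = {spec.bait_name: [int(spec.bait_counts[c]) for c in conditions]}
    for prey in spec.prey_rates:  # insertion order fixes the stream order
        rates = np.array([spec.prey_rates[prey][c] for c in conditions], dtype=float)
        rows[prey] = rng.poisson(rates).tolist()
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=conditions)
    counts.index.name = "protein"
    return SpectralCountTable(counts=counts, bait=spec.bait_name)


@dataclass
class PhosphoSpec:
    """Latent truth for phosphopeptide intensity quartets.

    ``efficiencies`` are the four latent ionization efficiencies
    (E0 base, E1 mod, E2 base-normalizer, E3 mod-normalizer): measured
    intensity is concentration / E. Each (phase, replicate) run carries a
    log-normal spray scale factor (cv ``run_scale_cv``) common to all four
    intensities, and each intensity an independent log-normal measurement
    error with coefficient of variation ``noise_cv``.
    """

    occupancy_per_phase: Mapping[str, float]
    efficiencies: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    protein_amount_per_phase: Mapping[str, float] | None = None
    noise_cv: float = 0.0
    run_scale_cv: float = 0.25
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for phase, occ in self.occupancy_per_phase.items():
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy for {phase!r} outside [0, 1]")
        if any(e <= 0 for e in self.efficiencies):
            raise ValueError("ionization efficiencies must be > 0")
        if self.protein_amount_per_phase is None:
            self.protein_amount_per_phase = {p: 1.0 for p in self.occupancy_per_phase}
        if self.noise_cv < 0 or self.run_scale_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def gen_phospho_intensities(
    spec: PhosphoSpec,
) -> dict[str, list[PhosphoIntensityQuartet]]:
    """Generate replicate intensity quartets per phase.

    Noiseless concentrations: mod = occupancy * amount, base =
    (1 - occupancy) * amount, both normalizers = amount. Intensities are
    concentration / E times the run scale times independent measurement
    noise. At ``noise_cv = 0`` the occupancy-odds ratio between any two
    phases is recovered exactly by the occupancy calculus, whatever the
    efficiencies and run scales.
    """
    rng = np.random.default_rng(spec.seed)
    e0, e1, e2, e3 = spec.efficiencies
    sig_noise = _lognormal_sigma(spec.noise_cv)
    sig_run = _lognormal_sigma(spec.run_scale_cv)
    out: dict[str, list[PhosphoIntensityQuartet]] = {}
    for phase in spec.occupancy_per_phase:  # documented stream order
        occ = spec.occupancy_per_phase[phase]
        amount = spec.protein_amount_per_phase[phase]
        reps = []
        for r in range(spec.n_replicates):
            run = rng.lognormal(0.0, sig_run) if sig_run > 0 else 1.0
            noise = (
                rng.lognormal(0.0, sig_noise, size=4)
                if sig_noise > 0
                else np.ones(4)
            )
            reps.append(
                PhosphoIntensityQuartet(
                    I0=(1.0 - occ) * amount / e0 * run * noise[0],
                    I1=occ * amount / e1 * run * noise[1],
                    I2=amount / e2 * run * noise[2],
                    I3=amount / e3 * run * noise[3],
                    condition=phase,
                )
            )
        out[phase] = reps
    return out


def gen_read_alignments(
    exon_defs: Sequence[ExonDef],
    expression_levels: Sequence[float],
    n_reads: int,
    read_len: int = 50,
    seed: int = 0,
) -> tuple[list[tuple[int, int]], int]:
    """Place reads inside exons proportional to expression level.

    Returns (alignments, total_aligned_reads); the total is the library-size
    denominator for RPKM. Reads are drawn per exon with probability
    proportional to ``expression * exon length`` (uniform coverage at equal
    expression) and placed uniformly so they fit inside the exon; exons
    shorter than the read length are covered end to end.
    """
    expr = np.asarray(expression_levels, dtype=float)
    if len(exon_defs) != expr.size:
        raise ValueError("one expression level per exon required")
    if np.any(expr < 0):
        raise ValueError("expression levels must be non-negative")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return [], 0
    weights = expr * np.array([e.length_bp for e in exon_defs], dtype=float)
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError("total expression is zero; no reads can be placed")
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(exon_defs), size=n_reads, p=weights / total_w)
    alignments = []
    for idx in choice:
        exon = exon_defs[idx]
        if exon.length_bp <= read_len:
            alignments.append((exon.start, exon.end))
        else:
            start = int(rng.integers(exon.start, exon.end - read_len + 1))
            alignments.append((start, start + read_len))
    return alignments, n_reads


# ---------------------------------------------------------------------------
# writers: the same TSV/BED dialects the analysis modules read


def write_exon_quant(usage: ExonUsageMatrix, path) -> None:
    """Write RPKM values as a long TSV: barcode, exon_id, rpkm."""
    long = usage.rpkm.stack().rename("rpkm").reset_index()
    long.columns = ["barcode", "exon_id", "rpkm"]
    long.to_csv(path, sep="\t", index=False)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    cols = [
        "barcode",
        "vital_status",
        "days_to_death",
        "days_to_last_followup",
        "er_status",
        "her2_status",
    ]
    clinical[[c for c in cols if c in clinical.columns]].to_csv(path, sep="\t", index=False)


def write_bed(exons: Sequence[ExonDef], path) -> None:
    with open(path, "w") as fh:
        for e in exons:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\texon_{e.exon_id}\n")


def write_count_table(table: SpectralCountTable, path) -> None:
    table.counts.to_csv(path, sep="\t")


def write_phospho_csv(quartets: Mapping[str, Sequence[PhosphoIntensityQuartet]], path) -> None:
    """Write intensity quartets as CSV: replicate, phase, I0, I1, I2, I3."""
    rows = []
    for phase, reps in quartets.items():
        for i, q in enumerate(reps, start=1):
            rows.append(
                {"replicate": i, "phase": phase, "I0": q.I0, "I1": q.I1, "I2": q.I2, "I3": q.I3}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
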