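"""Bait-normalized spectral-count statistics for IP-LC/MS prey proteins.

In an affinity-purification LC-MS/MS screen the bait protein's spectral
counts measure how much material each pull-down recovered. A prey protein
that associates equally well with every bait variant should therefore
distribute its spectral counts across conditions *like the bait does*.
This module tests that null two ways:

* a chi-squared test of independence on the 2x2 table (prey, bait) x
  (condition A, condition B) with Yates continuity correction, the
  correction term floored at zero;
* a G test (log-likelihood ratio) of the observed prey counts against
  bait-derived expected counts across any number of conditions.

The floor on the Yates term matters: for a prey whose counts track the
bait almost perfectly, |O - E| can be smaller than the 0.5 correction and
an unfloored correction would manufacture a spurious statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpectralCountTable",
    "PreyTestResult",
    "chi2_yates_2x2",
    "expected_from_bait",
    "g_test",
    "prey_tests",
    "volcano_table",
    "read_count_table",
]


@dataclass
class SpectralCountTable:
    """Bait and prey spectral counts per IP condition.

    ``counts`` has one row per protein (bait row included) and one column
    per condition, non-negative integers.
    """

    counts: pd.DataFrame
    bait: str

    def __post_init__(self) -> None:
        if self.bait not in self.counts.index:
            raise ValueError(f"bait row {self.bait!r} missing from count table")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("spectral counts must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def bait_counts(self) -> pd.Series:
        return self.counts.loc[self.bait]

    @property
    def prey_ids(self) -> list[str]:
        return [p for p in self.counts.index if p != self.bait]


@dataclass
class PreyTestResult:
    protein: str
    chi2: float
    p_chi2: float
    g_stat: float
    p_g: float
    df: int
    expectation_source: str
    expected: np.ndarray = field(repr=False, default=None)


def chi2_yates_2x2(
    prey_counts: tuple[float, float], bait_counts: tuple[float, float]
) -> tuple[float, float]:
    """Yates-corrected chi-squared on the 2x2 (prey, bait) x conditions table.

    Expected counts come from the row/column marginals; each cell
    contributes ``max(0, |O - E| - 0.5)**2 / E``. Returns (statistic,
    right-tail p on 1 df).
    """
    observed = np.array([prey_counts, bait_counts], dtype=float)
    if observed.shape != (2, 2):
        raise ValueError("chi2_yates_2x2 needs exactly two counts per row")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    expected = row * col / total
    adj = np.maximum(0.0, np.abs(observed - expected) - 0.5)
    chi2 = float((adj**2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def expected_from_bait(
    prey_counts: np.ndarray | list[float], bait_counts: np.ndarray | list[float]
) -> np.ndarray:
    """Expected prey counts if the prey distributed across conditions like the bait.

    ``E_c = sum(prey) * bait_c / sum(bait)``.
    """
    prey = np.asarray(prey_counts, dtype=float)
    bait = np.asarray(bait_counts, dtype=float)
    if prey.shape != bait.shape:
        raise ValueError("prey and bait must cover the same conditions")
    if (bait < 0).any() or (prey < 0).any():
        raise ValueError("counts must be non-negative")
    bait_total = bait.sum()
    if bait_total <= 0:
        raise ValueError("bait counts sum to zero; no expectation derivable")
    return prey.sum() * bait / bait_total


def g_test(
    observed: np.ndarray | list[float], expected: np.ndarray | list[float]
) -> tuple[float, float]:
    """Log-likelihood-ratio (G) test of observed vs expected counts.

    ``G = 2 * sum(O * ln(O / E))`` with the ``0 * ln(0)`` terms taken as
    zero; p is the right tail of chi-squared on (number of conditions - 1)
    degrees of freedom.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and expected must be matching vectors of >= 2 conditions")
    if ((exp == 0) & (obs > 0)).any():
        raise ValueError("observed > 0 where expected = 0: G undefined")
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))
    g = max(g, 0.0)
    df = obs.size - 1
    return g, float(stats.chi2.sf(g, df=df))


def prey_tests(
    table: SpectralCountTable,
    conditions: tuple[str, str] | None = None,
) -> list[PreyTestResult]:
    """Run the 2x2 Yates chi-squared and the G test for every prey protein.

    The chi-squared uses the two named ``conditions`` (default: the last
    two columns, the mutant pair in the canonical layout) against the bait
    row of the same assay. The G test uses the same condition pair with
    bait-derived expected counts.
    """
    conds = list(conditions) if conditions else table.conditions[-2:]
    missing = [c for c in conds if c not in table.conditions]
    if missing:
        raise ValueError(f"conditions not in table: {missing}")
    bait = table.bait_counts[conds].to_numpy(dtype=float)
    results = []
    for prey in table.prey_ids:
        obs = table.counts.loc[prey, conds].to_numpy(dtype=float)
        chi2, p_chi2 = chi2_yates_2x2(tuple(obs), tuple(bait))
        expected = expected_from_bait(obs, bait)
        if obs.sum() > 0:
            g, p_g = g_test(obs, expected)
        else:
            g, p_g = 0.0, 1.0
        results.append(
            PreyTestResult(
                protein=prey,
                chi2=chi2,
                p_chi2=p_chi2,
                g_stat=g,
                p_g=p_g,
                df=len(conds) - 1,
                expectation_source=table.bait,
                expected=expected,
            )
        )
    return results


def volcano_table(
    table: SpectralCountTable,
    conditions: tuple[str, str] | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-prey log2 fold change and -log10 p for a volcano plot.

    ``lfc = log2((count_B + q) / (count_A + q))`` for the condition pair
    (A, B); the p-value is the Yates 2x2 chi-squared against the bait row.
    """
    conds = list(conditions) if conditions else table.conditions[-2:]
    results = prey_tests(table, tuple(conds))
    rows = []
    for res in results:
        a, b = (float(table.counts.loc[res.protein, c]) for c in conds)
        lfc = np.log2((b + pseudocount) / (a + pseudocount))
        rows.append(
            {
                "protein": res.protein,
                f"count_{conds[0]}": a,
                f"count_{conds[1]}": b,
                "log2_fold_change": lfc,
                "neg_log10_p": -np.log10(res.p_chi2) if res.p_chi2 > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows).set_index("protein")


def read_count_table(path, bait: str) -> SpectralCountTable:
    """Read a spectral-count TSV: first column protein id, one column per condition."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df = df.apply(pd.to_numeric)
    return SpectralCountTable(counts=df, bait=bait)
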