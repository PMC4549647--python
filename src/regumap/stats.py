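"""Set-level statistics: fold enrichment, exact goodness of fit, and
Yates-corrected chi-square comparisons of mark overlap between cell types.

The 2x2 chi-square with Yates' continuity correction is implemented
directly (it is the statistic the pipeline reports)::

    X2 = sum over cells of max(|O - E| - 0.5, 0)**2 / E,   df = 1

with expecteds from the row/column margins and the correction clamped at
zero when |O - E| < 0.5 (so the corrected statistic can never exceed the
uncorrected Pearson statistic).  p-values come from the chi-square
distribution with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import overlaps
from .io import PeakTrack, Variant


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns mark present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.float64)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    dof: int = 1


def yates_chi2(table: ContingencyTable2x2) -> Chi2Result:
    """Pearson chi-square with Yates' continuity correction on a 2x2 table.

    A zero row or column margin leaves the test undefined and raises.
    Expected counts below 5 only trigger a warning — the caller may prefer
    :func:`fisher_exact` there.
    """
    obs = table.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    exp = np.outer(rows, cols) / obs.sum()
    if (exp < 5).any():
        warnings.warn(
            "expected cell count below 5; Yates chi-square is unreliable, "
            "consider Fisher's exact test",
            stacklevel=2,
        )
    corrected = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    stat = float((corrected**2 / exp).sum())
    return Chi2Result(stat, float(sps.chi2.sf(stat, df=1)))


def pearson_chi2(table: ContingencyTable2x2) -> Chi2Result:
    """Uncorrected Pearson chi-square (reference for the Yates <= Pearson bound)."""
    obs = table.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    exp = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    return Chi2Result(stat, float(sps.chi2.sf(stat, df=1)))


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p, the small-count fallback."""
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


@dataclass(frozen=True)
class GofResult:
    """Goodness of fit of an observed count against an expected rate."""

    k: int
    n: int
    expected_rate: float
    p_lower: float        # exact binomial lower tail P(X <= k)
    p_two_sided: float    # exact binomial two-sided
    p_chi2: float         # 1-df chi-square goodness of fit, the asymptotic alternative


def gof_expected_rate(k_unflagged: int, n: int, expected_rate: float) -> GofResult:
    """Test an observed count ``k`` of ``n`` against a known expected rate.

    The primary p-value is the exact binomial lower tail
    ``P(X <= k | n, expected_rate)`` — "is the observed count significantly
    *lower* than expected" — with the exact two-sided p and a chi-square
    goodness-of-fit p reported alongside.
    """
    if not (0 <= k_unflagged <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < expected_rate < 1):
        raise ValueError("expected_rate must be in (0, 1)")
    p_lower = float(sps.binom.cdf(k_unflagged, n, expected_rate))
    p_two = float(sps.binomtest(k_unflagged, n, expected_rate).pvalue)
    obs = np.array([k_unflagged, n - k_unflagged], dtype=np.float64)
    exp = np.array([n * expected_rate, n * (1 - expected_rate)])
    chi = float(((obs - exp) ** 2 / exp).sum())
    p_chi2 = float(sps.chi2.sf(chi, df=1))
    return GofResult(k_unflagged, n, expected_rate, p_lower, p_two, p_chi2)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold enrichment of a variant set in a track, with a one-sided p."""

    n_query: int
    k_query: int
    background_rate: float
    fold: float
    p_value: float
    method: str
    fold_ci_low: float
    fold_ci_high: float


def _overlap_count(variants: Sequence[Variant], track: PeakTrack) -> int:
    return sum(1 for v in variants if overlaps(v, track))


def fold_enrichment(
    query: Sequence[Variant],
    track: PeakTrack,
    background: float | Sequence[Variant],
    method: str = "binomial",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Fold enrichment of query-variant overlap with a track over background.

    ``background`` is either an overlap rate in (0, 1) or a background
    variant set whose overlap rate defines the null.  ``fold`` is
    ``(k/n) / rate``.  The p-value is the one-sided upper tail: binomial
    ``P(X >= k | n, rate)``, or the add-one-smoothed fraction of ``n_perm``
    resampled background sets of size ``n`` with overlap >= k.  The 95%
    interval on fold is Clopper-Pearson on ``k/n`` divided by the rate.
    """
    n = len(query)
    if n == 0:
        raise ValueError("empty query set")
    if method not in ("binomial", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    k = _overlap_count(query, track)
    bg_set: list[Variant] | None = None
    if isinstance(background, (int, float)):
        rate = float(background)
        if not (0 <= rate < 1):
            raise ValueError("background rate must be in [0, 1)")
    else:
        bg_set = list(background)
        if not bg_set:
            raise ValueError("empty background set")
        rate = _overlap_count(bg_set, track) / len(bg_set)
    if rate == 0.0:
        if k > 0:
            raise ValueError("background rate is 0 with overlapping query: infinite fold")
        return EnrichmentResult(n, 0, 0.0, 0.0, 1.0, method, 0.0, np.nan)
    fold = (k / n) / rate
    ci_prop = sps.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    ci = (ci_prop.low / rate, ci_prop.high / rate)
    if method == "binomial":
        p = float(sps.binom.sf(k - 1, n, rate))  # P(X >= k)
    else:
        rng = np.random.default_rng(seed)
        if bg_set is not None:
            hits = np.array([overlaps(v, track) for v in bg_set])
            draws = rng.integers(0, len(bg_set), size=(n_perm, n))
            perm_k = hits[draws].sum(axis=1)
        else:
            perm_k = rng.binomial(n, rate, size=n_perm)
        p = float((1 + int((perm_k >= k).sum())) / (1 + n_perm))
    return EnrichmentResult(n, k, rate, fold, p, method, ci[0], ci[1])


def _track_lookup(tracks: Sequence[PeakTrack]) -> dict[tuple[str, str], PeakTrack]:
    return {(t.cell, t.mark): t for t in tracks if t.kind == "chip"}


def cross_cell_comparison(
    variants: Sequence[Variant],
    marks: Sequence[str],
    cells: Sequence[str],
    reference_cell: str,
    tracks: Sequence[PeakTrack],
    adjust: bool = False,
) -> pd.DataFrame:
    """Yates chi-square of per-mark variant overlap, each cell vs a reference.

    For every mark and every non-reference cell, the 2x2 table crosses
    (variant overlaps the mark / does not) with (cell / reference cell).
    Identical overlap counts give statistic 0 and p 1 (this covers the
    degenerate all-zero margin).  ``adjust=True`` appends Benjamini-
    Hochberg q-values across all rows.
    """
    if not variants:
        raise ValueError("empty variant set")
    if reference_cell not in cells:
        raise ValueError(f"reference cell {reference_cell!r} not among cells")
    lookup = _track_lookup(tracks)
    for cell in cells:
        for mark in marks:
            if (cell, mark) not in lookup:
                raise ValueError(f"no track for (cell={cell!r}, mark={mark!r})")
    n = len(variants)
    k_cache = {
        (cell, mark): _overlap_count(variants, lookup[(cell, mark)])
        for cell in cells
        for mark in marks
    }
    rows = []
    for mark in marks:
        k_ref = k_cache[(reference_cell, mark)]
        for cell in cells:
            if cell == reference_cell:
                continue
            k_c = k_cache[(cell, mark)]
            if k_c == k_ref:
                stat, p = 0.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = yates_chi2(ContingencyTable2x2(k_c, n - k_c, k_ref, n - k_ref))
                stat, p = res.statistic, res.p_value
            rows.append(
                {
                    "mark": mark,
                    "cell": cell,
                    "reference": reference_cell,
                    "a": k_c,
                    "b": n - k_c,
                    "c": k_ref,
                    "d": n - k_ref,
                    "chi2": stat,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    if adjust and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
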