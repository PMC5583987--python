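"""Negative-binomial exact-test differential expression between stages.

The two-group test conditions on the group total: with equal effective
library sizes, the conditional distribution of one group's sum given the
grand total is beta-binomial with shape parameters n_a/phi and n_b/phi
(binomial in the Poisson limit phi=0), and the two-sided p-value sums the
probabilities of all splits no more probable than the observed one.  The
common dispersion phi is estimated by maximizing the summed per-feature
conditional log-likelihood (qCML).  Multiple testing is controlled per
comparison with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, MirswitchError, ValidationError

__all__ = [
    "DEResult",
    "DispersionEstimate",
    "equalize_library_sizes",
    "estimate_common_dispersion",
    "exact_test",
    "bh_fdr",
    "run_pairwise_de",
    "de_results_frame",
]

#: relative tolerance when deciding whether a split is "as or less probable"
TIE_RTOL = 1e-10

PHI_BOUNDS = (1e-6, 10.0)


@dataclass(frozen=True)
class DEResult:
    """Differential expression of one feature in one stage comparison."""

    feature_id: str
    comparison: tuple[str, str]  # (stage_a, stage_b)
    mean_a: float
    mean_b: float
    log2fc: float  # b over a, pseudo-count 0.5 on normalized means
    p: float
    q: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0) or not (0.0 < self.q <= 1.0):
            raise ValidationError(f"{self.feature_id}: p/q outside (0, 1]")
        if self.q < self.p - 1e-12:
            raise ValidationError(f"{self.feature_id}: q < p")


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str  # "conditional_ML" | "fixed"
    n_features_used: int

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValidationError("dispersion must be >= 0")


# ---------------------------------------------------------------------------
# Library-size equalization (quantile adjustment to the geometric mean)
# ---------------------------------------------------------------------------


def equalize_library_sizes(
    counts: pd.DataFrame, library_sizes: Sequence[float], phi: float = 0.0
) -> tuple[pd.DataFrame, float]:
    """Map counts to pseudo-counts at a common (geometric-mean) library size.

    Each observed count is quantile-adjusted by matching moments of its NB
    distribution at the observed library size to the distribution at the
    common size: pseudo = mu_out + (y - mu_in) * sqrt(var_out/var_in), with
    mu proportional to the per-feature abundance estimate and var = mu(1 +
    phi*mu).  Equal input library sizes are a fixed point, and rescaling all
    library sizes by a constant leaves the pseudo-counts unchanged (the
    abundance estimate absorbs the scale).
    """
    libs = np.asarray(library_sizes, dtype=float)
    if (libs <= 0).any():
        raise ValidationError("library sizes must be > 0")
    common = float(np.exp(np.mean(np.log(libs))))
    y = counts.to_numpy(dtype=float)
    abundance = y.sum(axis=1, keepdims=True) / libs.sum()  # per-read abundance
    mu_in = abundance * libs[None, :]
    mu_out = abundance * common
    with np.errstate(divide="ignore", invalid="ignore"):
        var_in = mu_in * (1.0 + phi * mu_in)
        var_out = mu_out * (1.0 + phi * mu_out)
        scale = np.sqrt(np.where(var_in > 0, var_out / var_in, 1.0))
    pseudo = mu_out + (y - mu_in) * scale
    pseudo = np.clip(pseudo, 0.0, None)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


# ---------------------------------------------------------------------------
# Common dispersion (qCML)
# ---------------------------------------------------------------------------


def _cond_loglik(phi: float, group_counts: list[np.ndarray]) -> float:
    """Summed conditional log-likelihood of counts given group sums."""
    r = 1.0 / phi
    ll = 0.0
    for y in group_counts:  # features x replicates, one group
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        ll += float(
            gammaln(y + r).sum()
            - y.shape[0] * n * gammaln(r)
            + y.shape[0] * gammaln(n * r)
            - gammaln(z + n * r).sum()
        )
    return ll


def estimate_common_dispersion(
    pseudo_counts: pd.DataFrame, groups: Sequence[Sequence[str]]
) -> DispersionEstimate:
    """Maximize the conditional log-likelihood over phi in [1e-6, 10].

    ``groups`` lists the sample columns of each group; at least one group
    must have >= 2 replicates.  All-zero features are excluded.
    """
    group_arrays = []
    n_used = 0
    any_replicated = False
    nonzero = pseudo_counts.sum(axis=1) > 0
    kept = pseudo_counts.loc[nonzero]
    n_used = int(nonzero.sum())
    for cols in groups:
        if len(cols) >= 2:
            any_replicated = True
        group_arrays.append(kept[list(cols)].to_numpy(dtype=float))
    if not any_replicated:
        raise MirswitchError(
            "no group has replication; supply a fixed dispersion instead of estimating one"
        )
    res = minimize_scalar(
        lambda phi: -_cond_loglik(phi, group_arrays),
        bounds=PHI_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return DispersionEstimate(float(res.x), "conditional_ML", n_used)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def _split_raw_logpmf(t: int, n_a: int, n_b: int, phi: float, x: np.ndarray) -> np.ndarray:
    """Unnormalized log P(group-a sum = x | total = t) at equal library sizes.

    For phi > 0 this is the beta-binomial / negative-hypergeometric law with
    shapes r_a = n_a/phi and r_b = n_b/phi; phi = 0 is the binomial limit.
    Normalize against the integer grid 0..t.
    """
    if phi == 0.0:
        return (
            gammaln(t + 1)
            - gammaln(x + 1)
            - gammaln(t - x + 1)
            + x * np.log(n_a)
            + (t - x) * np.log(n_b)
        )
    r_a, r_b = n_a / phi, n_b / phi
    return (
        gammaln(x + r_a)
        - gammaln(x + 1)
        + gammaln(t - x + r_b)
        - gammaln(t - x + 1)
    )


def _split_logpmf(t: int, n_a: int, n_b: int, phi: float, k: np.ndarray) -> np.ndarray:
    grid = np.arange(t + 1, dtype=float)
    norm = logsumexp(_split_raw_logpmf(t, n_a, n_b, phi, grid))
    return _split_raw_logpmf(t, n_a, n_b, phi, k) - norm


def exact_test(
    counts_a: Sequence[float], counts_b: Sequence[float], phi: float
) -> float:
    """Two-sided conditional exact test for two NB groups at equal libraries.

    p = sum of the conditional probabilities of all splits of the grand total
    whose probability is <= that of the observed split (relative tie
    tolerance 1e-10).  phi=0 reduces to the conditional binomial test.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("negative counts")
    if phi < 0:
        raise ValidationError("dispersion must be >= 0")
    s_a, s_b = float(a.sum()), float(b.sum())
    t_int = int(round(s_a + s_b))
    if t_int == 0:
        return 1.0
    n_a, n_b = len(a), len(b)
    grid = np.arange(t_int + 1, dtype=float)
    raw_grid = _split_raw_logpmf(t_int, n_a, n_b, phi, grid)
    norm = logsumexp(raw_grid)
    log_grid = raw_grid - norm
    log_obs = float(_split_raw_logpmf(t_int, n_a, n_b, phi, np.array([s_a]))[0]) - norm
    keep = log_grid <= log_obs + np.log1p(TIE_RTOL)
    if keep.any():
        p = float(np.exp(logsumexp(log_grid[keep])))
    else:  # non-integer observed split more extreme than any grid point
        p = float(np.exp(log_obs))
    return min(max(p, 1e-300), 1.0)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Pairwise stage comparisons
# ---------------------------------------------------------------------------


def run_pairwise_de(
    counts: CountMatrix,
    comparisons: Sequence[tuple[str, str]],
    fold_cutoff: float = 2.0,
    fdr: float = 0.05,
    fixed_dispersion: float | None = None,
    detected_features: set[str] | None = None,
) -> dict[tuple[str, str], list[DEResult]]:
    """Exact-test DE for each stage comparison.

    Per comparison: equalize library sizes -> estimate the common dispersion
    (or use the supplied fixed value; required for unreplicated designs) ->
    exact test per detected feature -> BH within the comparison.  A feature is
    significant iff |log2fc| > log2(fold_cutoff) and q < fdr.
    """
    sheet = counts.samples
    for a, b in comparisons:
        for st in (a, b):
            if st not in sheet.stage_order:
                raise ValidationError(f"comparison references unknown stage {st!r}")
    mat = counts
    if detected_features is not None:
        mat = counts.subset_features(detected_features)

    out: dict[tuple[str, str], list[DEResult]] = {}
    lib_by_sample = sheet.library_size_by_sample
    lfc_cut = float(np.log2(fold_cutoff))
    for a, b in comparisons:
        cols_a = sheet.samples_for_stage(a)
        cols_b = sheet.samples_for_stage(b)
        if not cols_a or not cols_b:
            raise ValidationError(f"comparison ({a}, {b}) has an empty group")
        sub = mat.counts[cols_a + cols_b]
        libs = [lib_by_sample[s] for s in cols_a + cols_b]
        replicated = len(cols_a) >= 2 or len(cols_b) >= 2
        if fixed_dispersion is not None:
            phi = float(fixed_dispersion)
        elif replicated:
            pseudo0, _ = equalize_library_sizes(sub, libs)
            phi = estimate_common_dispersion(pseudo0, [cols_a, cols_b]).phi
        else:
            raise MirswitchError(
                f"comparison ({a}, {b}) is unreplicated; a fixed dispersion is required"
            )
        pseudo, common_lib = equalize_library_sizes(sub, libs, phi=phi)

        ya = pseudo[cols_a].to_numpy(dtype=float)
        yb = pseudo[cols_b].to_numpy(dtype=float)
        mean_a = ya.mean(axis=1) / common_lib * 1e6
        mean_b = yb.mean(axis=1) / common_lib * 1e6
        log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)

        pvals = np.array(
            [exact_test(ya[i], yb[i], phi) for i in range(len(sub.index))], dtype=float
        )
        qvals = bh_fdr(pvals)
        results = []
        for i, fid in enumerate(sub.index):
            sig = bool(abs(log2fc[i]) > lfc_cut and qvals[i] < fdr)
            results.append(
                DEResult(
                    str(fid), (a, b), float(mean_a[i]), float(mean_b[i]),
                    float(log2fc[i]), float(pvals[i]), float(qvals[i]), sig,
                )
            )
        out[(a, b)] = results
    return out


def de_results_frame(results: dict[tuple[str, str], list[DEResult]]) -> pd.DataFrame:
    rows = []
    for (a, b), rs in results.items():
        for r in rs:
            rows.append(
                {
                    "feature_id": r.feature_id,
                    "stage_a": a,
                    "stage_b": b,
                    "mean_a": r.mean_a,
                    "mean_b": r.mean_b,
                    "log2fc": r.log2fc,
                    "p": r.p,
                    "q": r.q,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "stage_a", "stage_b", "mean_a", "mean_b",
            "log2fc", "p", "q", "significant",
        ],
    )
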