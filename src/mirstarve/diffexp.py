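"""No-replicate differential expression for a two-library count matrix.

The design is one "well-fed" and one "starved" library with no biological
replicates, so the negative-binomial dispersion cannot be estimated and is
fixed by the analyst (phi = 0.1, the edgeR "common dispersion" convention,
variance = mu + phi*mu^2).  The pipeline is:

    counts (mature + hairpin rows)
      -> TMM normalization factors
      -> CPM, keep features with >= 1 CPM in at least one library
      -> conditional NB exact test at fixed phi
      -> Benjamini-Hochberg FDR (step-up, m = number of features tested)
      -> signed fold change (higher CPM / lower CPM, sign from the log2FC)

The exact test equalizes the two libraries to a common effective size (the
geometric mean), rounds to integer pseudo-counts, and conditions on their
sum s: under two independent NB variables with equal means and dispersion
phi, the conditional law of one given the sum is beta-binomial-like and free
of the mean; the two-sided p-value sums the probabilities of all splits no
more likely than the observed one.  At phi = 0 this reduces exactly to the
conditional binomial(s, 1/2) test.  This is a documented simplification of
edgeR's qCML machinery: the conditional enumeration itself, not bitwise
equality with edgeR, is the contract (tests check it against brute-force
enumeration and the binomial special case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .quantify import CountTable

DE_CLASSES = ("mature", "hairpin")


@dataclass
class DEConfig:
    common_dispersion: float = 0.1
    cpm_threshold: float = 1.0
    fdr_threshold: float = 0.05
    tmm_logratio_trim: float = 0.30
    tmm_abs_trim: float = 0.05
    prior_count: float = 0.125  # proportional prior per library-size-scaled unit

    def __post_init__(self) -> None:
        if self.common_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for trim in (self.tmm_logratio_trim, self.tmm_abs_trim):
            if not (0 <= trim < 0.5):
                raise ValueError("TMM trims must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# normalization


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference library.

    Weighted trimmed mean of M-values: M = log2 relative-proportion ratio,
    A = mean log2 proportion; features zero in either library are excluded,
    then `logratio_trim` is trimmed from each tail of M and `abs_trim` from
    each tail of A; weights are inverse asymptotic (delta-method) variances.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.log2((obs / lib_obs) / (ref / lib_ref))
        absE = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(logR) & np.isfinite(absE) & (absE > -1e10)
    logR, absE, v = logR[finite], absE[finite], v[finite]
    if logR.size == 0:
        return 1.0
    if np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(logR)
    rank_a = rankdata(absE)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not np.any(keep):
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_library: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-library TMM scaling factors, normalized to geometric mean 1.

    `counts` is features x libraries.  When `ref_library` is None the library
    whose upper-quartile CPM is closest to the mean upper quartile is the
    reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    mat = counts.to_numpy(dtype=float)
    lib_sizes = mat.sum(axis=0)
    if np.any(lib_sizes <= 0):
        raise ValueError("library with zero total count")
    if ref_library is None:
        nonzero = mat[mat.sum(axis=1) > 0]
        uq = np.array(
            [np.quantile(nonzero[:, j] / lib_sizes[j], 0.75) for j in range(mat.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_library)

    factors = np.array(
        [
            _tmm_pair_factor(
                mat[:, j], mat[:, ref_idx], lib_sizes[j], lib_sizes[ref_idx],
                logratio_trim, abs_trim,
            )
            if j != ref_idx
            else 1.0
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over effective (TMM-scaled) library sizes."""
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise ValueError("library with zero total count")
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = lib_sizes * factors
    return counts.div(eff, axis=1) * 1e6


def filter_expressed(cpm_table: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Features with CPM >= threshold (inclusive) in at least one library."""
    keep = (cpm_table >= threshold).any(axis=1)
    return cpm_table.index[keep]


# ---------------------------------------------------------------------------
# the conditional NB exact test


def _conditional_log_pmf(s: int, phi: float) -> np.ndarray:
    """log P(K = k | K + K' = s) for k = 0..s, K, K' iid NB(mean mu, disp phi).

    The conditional law is free of mu.  For phi > 0 with r = 1/phi it is the
    ratio of NB ancillary terms (beta-binomial form); at phi = 0 it is
    binomial(s, 1/2).
    """
    k = np.arange(s + 1)
    if phi == 0:
        logp = gammaln(s + 1) - gammaln(k + 1) - gammaln(s - k + 1) - s * math.log(2.0)
    else:
        r = 1.0 / phi
        logp = (
            gammaln(k + r) - gammaln(k + 1)
            + gammaln(s - k + r) - gammaln(s - k + 1)
        )
        logp -= logsumexp(logp)
    return logp


def exact_test_nb(
    count_a: float,
    count_b: float,
    eff_size_a: float,
    eff_size_b: float,
    phi: float = 0.1,
    prior_count: float = 0.125,
) -> tuple[float, float]:
    """(log2 fold change B vs A, two-sided conditional p-value).

    Counts are rescaled to the common effective size (geometric mean of the
    two effective sizes) and rounded to integer pseudo-counts; conditioning on
    the pseudo-count sum, the two-sided p sums the conditional probabilities
    of all splits no more likely than the observed one.  The log2FC uses a
    small proportional prior (prior_count per library-size-scaled unit) to
    tame zeros.
    """
    if min(count_a, count_b) < 0 or min(eff_size_a, eff_size_b) <= 0 or phi < 0:
        raise ValueError("negative counts/dispersion or non-positive sizes")

    common = math.sqrt(eff_size_a * eff_size_b)
    ka = int(round(count_a * common / eff_size_a))
    kb = int(round(count_b * common / eff_size_b))

    mean_eff = (eff_size_a + eff_size_b) / 2.0
    prior_a = prior_count * eff_size_a / mean_eff
    prior_b = prior_count * eff_size_b / mean_eff
    log2fc = math.log2((count_b + prior_b) / (eff_size_b + 2 * prior_b)) - math.log2(
        (count_a + prior_a) / (eff_size_a + 2 * prior_a)
    )

    s = ka + kb
    if s == 0:
        return log2fc, 1.0
    logp = _conditional_log_pmf(s, phi)
    # probability-mass method: outcomes no more likely than the observed split
    obs = logp[ka]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return log2fc, min(p, 1.0)


# ---------------------------------------------------------------------------
# multiple testing and fold change


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    `m` may exceed the list length to model additional untested hypotheses
    (implicitly p = 1); q(i) = min_{j >= i} min(p(j) * m / j, 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def signed_fold_change(
    cpm_a: float, cpm_b: float, log2fc: float, zero_substitute: float | None = None
) -> float:
    """Higher CPM over lower CPM, carrying the sign of the log2FC.

    When the smaller CPM is exactly zero, `zero_substitute` (e.g. the
    prior-derived CPM) replaces it before dividing; with both zero the ratio
    is undefined.
    """
    if cpm_a < 0 or cpm_b < 0:
        raise ValueError("CPMs must be non-negative")
    if cpm_a == 0 and cpm_b == 0:
        raise ValueError("fold change undefined for two zero CPMs")
    lo, hi = min(cpm_a, cpm_b), max(cpm_a, cpm_b)
    if lo == 0:
        if zero_substitute is None or zero_substitute <= 0:
            raise ValueError("zero CPM requires a positive zero_substitute")
        lo = zero_substitute
    ratio = hi / lo
    return math.copysign(ratio, log2fc) if log2fc != 0 else ratio


# ---------------------------------------------------------------------------
# the full pipeline


@dataclass
class DEOutcome:
    results: pd.DataFrame        # feature_id, class, cpm_A, cpm_B, log2fc, p, fdr, fc
    ma_table: pd.DataFrame       # feature_id, A, M, significant
    tmm: pd.Series
    n_tested: int
    library_a: str = ""
    library_b: str = ""


def run_de(table: CountTable, cfg: DEConfig | None = None) -> DEOutcome:
    """CPM -> filter -> TMM -> exact test -> BH -> signed FC, two libraries.

    Only mature and hairpin rows enter the matrix (the miRNA-space test); the
    CPM denominator is the column total of that matrix.  Results are sorted
    by p-value; the MA table covers every tested feature (A = mean log2 CPM
    with the zero-taming prior, M = log2FC).
    """
    cfg = cfg or DEConfig()
    frame = table.to_frame(decimals=6)
    frame = frame[frame["class"].isin(DE_CLASSES)]
    libs = table.libraries
    if len(libs) != 2:
        raise ValueError("the no-replicate design needs exactly two libraries")
    lib_a, lib_b = libs
    counts = frame.set_index("feature_id")[libs].astype(float)
    classes = frame.set_index("feature_id")["class"]
    if counts.empty or (counts.sum(axis=0) <= 0).any():
        raise ValueError("empty or degenerate mature+hairpin count matrix")

    factors = tmm_factors(
        counts, logratio_trim=cfg.tmm_logratio_trim, abs_trim=cfg.tmm_abs_trim
    )
    cpm_table = cpm(counts, factors)
    kept = filter_expressed(cpm_table, cfg.cpm_threshold)
    if kept.empty:
        empty = pd.DataFrame(
            columns=["feature_id", "class", f"cpm_{lib_a}", f"cpm_{lib_b}",
                     "log2fc", "p_value", "fdr", "fc"]
        )
        return DEOutcome(empty, empty, factors, 0, lib_a, lib_b)

    lib_sizes = counts.sum(axis=0)
    eff = (lib_sizes * factors).to_dict()
    mean_eff = (eff[lib_a] + eff[lib_b]) / 2.0

    rows = []
    for fid in kept:
        ca, cb = counts.at[fid, lib_a], counts.at[fid, lib_b]
        log2fc, p = exact_test_nb(
            ca, cb, eff[lib_a], eff[lib_b], cfg.common_dispersion, cfg.prior_count
        )
        rows.append((fid, classes[fid], cpm_table.at[fid, lib_a],
                     cpm_table.at[fid, lib_b], log2fc, p))
    res = pd.DataFrame(
        rows, columns=["feature_id", "class", f"cpm_{lib_a}", f"cpm_{lib_b}",
                       "log2fc", "p_value"]
    )
    res["fdr"] = bh_adjust(res["p_value"].to_numpy(), m=len(res))

    fcs = []
    for _, row in res.iterrows():
        a, b = row[f"cpm_{lib_a}"], row[f"cpm_{lib_b}"]
        # prior-derived CPM of the smaller library when one side is zero
        zero_sub = cfg.prior_count / mean_eff * 1e6
        fcs.append(signed_fold_change(a, b, row["log2fc"], zero_substitute=zero_sub))
    res["fc"] = fcs
    res = res.sort_values("p_value", kind="mergesort").reset_index(drop=True)

    prior_cpm = cfg.prior_count / mean_eff * 1e6
    ma = pd.DataFrame(
        {
            "feature_id": res["feature_id"],
            "A": 0.5 * (np.log2(res[f"cpm_{lib_a}"] + prior_cpm)
                        + np.log2(res[f"cpm_{lib_b}"] + prior_cpm)),
            "M": res["log2fc"],
            "significant": res["fdr"] < cfg.fdr_threshold,
        }
    )
    return DEOutcome(res, ma, factors, len(res), lib_a, lib_b)


def format_results(res: pd.DataFrame, lib_a: str, lib_b: str) -> pd.DataFrame:
    """Display rounding: CPM/log2FC/FC at 1 d.p., p/FDR in 2-sig-fig sci."""
    out = res.copy()
    for col in (f"cpm_{lib_a}", f"cpm_{lib_b}", "log2fc", "fc"):
        out[col] = out[col].map(lambda x: round(float(x), 1))
    for col in ("p_value", "fdr"):
        out[col] = out[col].map(lambda x: float(f"{x:.1e}"))
    return out
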