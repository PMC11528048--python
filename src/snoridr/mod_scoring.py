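"""RiboMethSeq and HydraPsiSeq modification scores.

MethScore (a.k.a. ScoreC2, +/-2-bond window): the fraction of molecules
2'-O-methylated at a site, inferred from the local drop in combined
5'/3'-end counts at the protected bond,

    score = clamp(1 - c_site / mu, 0, 1),
    mu = (mean of the 2 bonds left + mean of the 2 bonds right) / 2.

PsiScore: the fraction pseudouridylated at a U position, inferred from the
hydrazine 5'-end count normalized to the local A/C/G background
(NormUcount) and then to the median over all uridines,

    NormUcount(p) = n5(p') / mean(n5 over non-U positions in a 10-nt window),
    score(p)      = clamp(1 - NormUcount(p) / median_U(NormUcount), 0, 1).

The median baseline assumes at most ~20% of uridines are modified.
Undefined values propagate as NaN with a reason code rather than silently
defaulting to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .end_profiles import CleavageProfile, EndCountProfile
from .quant_stats import significance_stars

logger = logging.getLogger(__name__)

HIGHLY_MODIFIED_THRESHOLD = 0.8


@dataclass
class MethScoreResult:
    position: int
    score: float  # NaN when undefined
    mu: float
    c_site: float
    reason: str | None = None  # set when score is NaN


def meth_score(
    bonds: CleavageProfile,
    position: int,
    halfwidth: int = 2,
    weighted: bool = False,
) -> MethScoreResult:
    """MethScore of the site at 1-based base ``position``.

    The methylated ribose at base ``n`` protects bond ``n`` (the bond 3' of
    it), so the site bond index equals the base position. ``mu`` is the
    symmetric neighbor mean over ``halfwidth`` bonds on each side
    (default 2: ScoreC2). With ``weighted=True`` the neighbor means are
    distance-weighted (1.0 for the closest bond, 0.9 for the next, ...),
    the down-weighting variant used by some RMS pipelines.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    n_bonds = bonds.n_bonds
    if not (1 <= position <= n_bonds):
        raise ValueError(f"position {position} outside bonds 1..{n_bonds}")
    if position - halfwidth < 1 or position + halfwidth > n_bonds:
        return MethScoreResult(position, math.nan, math.nan, float(bonds.c[position]), "window_out_of_bounds")
    left = bonds.c[position - halfwidth : position].astype(float)
    right = bonds.c[position + 1 : position + halfwidth + 1].astype(float)
    if weighted:
        wts = 1.0 - 0.1 * np.arange(halfwidth)  # distance 1 -> 1.0, distance 2 -> 0.9, ...
        mu = 0.5 * (np.average(left[::-1], weights=wts) + np.average(right, weights=wts))
    else:
        mu = 0.5 * (left.mean() + right.mean())
    c_site = float(bonds.c[position])
    if mu == 0:
        return MethScoreResult(position, math.nan, mu, c_site, "zero_neighbor_mean")
    score = min(max(1.0 - c_site / mu, 0.0), 1.0)
    return MethScoreResult(position, score, float(mu), c_site)


def norm_u_count(
    profile5: EndCountProfile,
    sequence: str,
    window: int = 10,
    offset: int = 0,
    min_non_u: int = 3,
) -> pd.DataFrame:
    """NormUcount profile over all uridines of ``sequence``.

    For a uridine at ``p`` the raw 5'-end count ``n5(p + offset)`` is
    divided by the mean count over non-U positions inside the ``window``-nt
    window centered on ``p``. Windows holding fewer than ``min_non_u``
    non-U positions are expanded symmetrically up to twice the nominal
    width, beyond which the value is NaN (reason ``no_background``).
    ``offset`` is the shared cleaved-base-to-counted-end convention and
    must match the value used when simulating/preparing the library.
    """
    if window < 4 or window % 2:
        raise ValueError("window must be even and >= 4")
    seq = np.array(list(sequence))
    L = seq.size
    if profile5.length != L:
        raise ValueError(f"profile length {profile5.length} != sequence length {L}")
    n5 = profile5.n5
    is_u = seq == "U"
    rows = []
    for p in (np.where(is_u)[0] + 1):
        p_prime = p + offset
        raw = float(n5[p_prime]) if 1 <= p_prime <= L else math.nan
        value, reason = math.nan, None
        if math.isnan(raw):
            reason = "offset_out_of_bounds"
        else:
            half = window // 2
            bg = None
            while half <= window:  # expansion cap: 2x nominal window
                lo, hi = max(1, p - half), min(L, p + half)
                span = np.arange(lo, hi + 1)
                non_u = span[~is_u[span - 1]]
                if non_u.size >= min_non_u:
                    bg = n5[non_u].mean()
                    break
                half += 1
            if bg is None:
                reason = "no_background"
            elif bg == 0:
                reason = "zero_background"
            else:
                value = raw / bg
        rows.append({"position": int(p), "raw": raw, "norm_u": value, "reason": reason})
    return pd.DataFrame(rows, columns=["position", "raw", "norm_u", "reason"])


def psi_score(norm_u: pd.DataFrame, min_defined: int = 10, skew_correction: bool = True) -> pd.DataFrame:
    """PsiScore per uridine from a NormUcount table.

    The unmodified baseline starts from the median NormUcount over all
    defined U positions -- robust provided modified uridines are a small
    minority (they contaminate only the lower tail). Because the score
    ratio must be mean-consistent (as MethScore's neighbor-mean is) while
    per-position cleavage biases make NormUcount right-skewed, the median
    is rescaled by ``exp(s**2 / 2)`` with ``s`` the log-normal spread
    estimated from the upper quartile (untouched by modified sites):
    ``s = (ln Q75 - ln median) / 0.6745``. On noise-free data the
    correction factor is ~1. Scores are
    ``clamp(1 - NormUcount / baseline, 0, 1)``.
    """
    defined = norm_u["norm_u"].dropna()
    if len(defined) < min_defined:
        raise ValueError(f"only {len(defined)} uridines with defined NormUcount; need >= {min_defined} for a baseline")
    m = float(defined.median())
    if skew_correction and m > 0:
        q75 = float(defined.quantile(0.75))
        if q75 > 0:
            s = (math.log(q75) - math.log(m)) / 0.6745
            m *= math.exp(0.5 * s * s)
    out = norm_u.copy()
    if m == 0:
        out["score"] = math.nan
        out["reason"] = out["reason"].fillna("zero_baseline")
    else:
        out["score"] = (1.0 - out["norm_u"] / m).clip(0.0, 1.0)
    out["baseline"] = m
    return out


def classify_highly_modified(score, threshold: float = HIGHLY_MODIFIED_THRESHOLD):
    """Strictly-greater-than-0.8 rule for "highly modified" sites.

    Accepts a scalar or an array/Series; NaN input yields NA output.
    """
    arr = pd.Series(np.atleast_1d(np.asarray(score, dtype=float)))
    out = pd.Series(pd.array(arr > threshold, dtype="boolean"))
    out[arr.isna()] = pd.NA
    if np.isscalar(score) or (hasattr(score, "ndim") and getattr(score, "ndim") == 0):
        return out.iloc[0]
    return out


def score_sites(
    sites: pd.DataFrame,
    scores_by_condition: dict[str, list[pd.Series]],
    mod_type: str,
) -> pd.DataFrame:
    """Average replicate scores per site per condition.

    Parameters
    ----------
    sites:
        Modification-site table (``position``, ``mod_type`` columns).
    scores_by_condition:
        ``{condition: [per-replicate Series indexed by 1-based position]}``;
        Nm sites must be scored with MethScore, Psi sites with PsiScore,
        so one call handles one ``mod_type``.
    mod_type:
        ``"Nm"`` or ``"Psi"``.

    Returns a long table with one row per (site, condition): the replicate
    mean (NaN replicates are dropped with a flag), the number of replicates
    used, and the highly-modified call on the mean.
    """
    if mod_type not in ("Nm", "Psi"):
        raise ValueError(f"unknown mod_type {mod_type!r}")
    sub = sites[sites["mod_type"] == mod_type]
    rows = []
    for condition, replicates in scores_by_condition.items():
        for _, site in sub.iterrows():
            pos = int(site["position"])
            vals = np.array([float(rep.get(pos, math.nan)) for rep in replicates])
            used = np.isfinite(vals)
            mean = float(vals[used].mean()) if used.any() else math.nan
            rows.append(
                {
                    "position": pos,
                    "mod_type": mod_type,
                    "condition": condition,
                    "score": mean,
                    "n_replicates": int(used.sum()),
                    "incomplete": bool((~used).any()),
                }
            )
    out = pd.DataFrame(rows)
    out["highly_modified"] = classify_highly_modified(out["score"].to_numpy())
    n_incomplete = int(out["incomplete"].sum())
    if n_incomplete:
        logger.warning("score_sites: %d site/condition means computed from incomplete replicates", n_incomplete)
    return out


@dataclass
class BoxSummary:
    """Box-plot summary: median, quartiles, 1.5-IQR whiskers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "BoxSummary":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_limit, hi_limit = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        return cls(
            n=v.size,
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            whisker_lo=float(v[v >= lo_limit].min()),
            whisker_hi=float(v[v <= hi_limit].max()),
        )


@dataclass
class ConditionComparison:
    statistic: float  # Mann-Whitney U of group A
    pvalue: float
    stars: str
    method: str
    summary_a: BoxSummary
    summary_b: BoxSummary
    n_dropped: int
    per_site_delta: pd.Series | None = None


def compare_conditions(
    scores_a,
    scores_b,
    exact_max_n: int = 8,
) -> ConditionComparison:
    """Unpaired two-sample Wilcoxon (Mann-Whitney) test between score sets.

    NaNs are dropped with a logged count. The exact null distribution is
    enumerated when both groups have at most ``exact_max_n`` values and no
    ties; larger samples use the mid-rank normal approximation (without
    continuity correction), keeping results platform-reproducible. When
    both inputs are Series over the same site index, the per-site
    difference (B - A) is attached.
    """
    a = pd.Series(scores_a, dtype=float)
    b = pd.Series(scores_b, dtype=float)
    delta = None
    if isinstance(scores_a, pd.Series) and isinstance(scores_b, pd.Series) and a.index.equals(b.index):
        delta = b - a
    av, bv = a.dropna().to_numpy(), b.dropna().to_numpy()
    n_dropped = (len(a) - av.size) + (len(b) - bv.size)
    if n_dropped:
        logger.warning("compare_conditions: dropped %d NaN scores", n_dropped)
    if av.size < 3 or bv.size < 3:
        raise ValueError("need at least 3 defined scores per group")
    no_ties = np.unique(np.concatenate([av, bv])).size == av.size + bv.size
    if max(av.size, bv.size) <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(av, bv, alternative="two-sided", method=method, use_continuity=False)
    return ConditionComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)),
        method=method,
        summary_a=BoxSummary.from_values(av),
        summary_b=BoxSummary.from_values(bv),
        n_dropped=n_dropped,
        per_site_delta=delta,
    )
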