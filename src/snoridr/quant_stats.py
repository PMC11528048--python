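"""Enrichment formulas and summary statistics.

Covers three unrelated but formula-level-simple quantifications used around
the sequencing core:

* ChIP-qPCR: triplicate-median Ct values, dilution-corrected delta-Ct and
  the IP/Input ratio ``2**(-dCt)``;
* TurboID proximity-labeling proteomics: per-purification median (nonzero)
  iBAQ normalization, Perseus-style down-shifted imputation of missing
  control values, log2 bait/control enrichment, and pairwise Welch tests
  between protein categories;
* microscopy ROI intensities: maximum signal, max/average ratio and
  nucleolus/nucleoplasm region ratios.

Significance stars follow the convention * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return "na"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# ChIP-qPCR
# ---------------------------------------------------------------------------

@dataclass
class QpcrRecord:
    """One qPCR target region with IP and input Ct triplicates.

    ``dilution`` is the total input dilution relative to the IP (the
    protocol's 10% chromatin fraction further diluted 1:50 gives the
    default 1/500).
    """

    region: str
    ct_ip: tuple
    ct_input: tuple
    dilution: float = 1.0 / 500.0

    def __post_init__(self) -> None:
        for name, vals in (("ct_ip", self.ct_ip), ("ct_input", self.ct_input)):
            vals = tuple(float(v) for v in vals)
            if not vals or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be non-empty positive Ct values")
            if len(vals) != 3:
                logger.warning("%s for %s has %d values (expected triplicate)", name, self.region, len(vals))
        if self.dilution <= 0:
            raise ValueError("dilution must be positive")


def qpcr_ratio(record: QpcrRecord) -> float:
    """IP/Input ratio from Ct triplicates.

    Medians are taken per triplicate first, then the input Ct is corrected
    for the dilution of the input sample relative to the IP:
    ``dCt = median(Ct_IP) - (median(Ct_input) - log2(1 / dilution))`` and
    ``ratio = 2**(-dCt)``. Equal IP and input medians mean the IP holds as
    much material as the *diluted* input, so the ratio is exactly the
    dilution fraction (1/500 = 0.002 at the default).
    """
    med_ip = float(np.median(record.ct_ip))
    med_input = float(np.median(record.ct_input))
    dct = med_ip - (med_input - math.log2(1.0 / record.dilution))
    return 2.0 ** (-dct)


def qpcr_table(df: pd.DataFrame, dilution: float | None = None) -> pd.DataFrame:
    """Vectorized qpcr_ratio over a table with ``ct_ip_1..3`` /
    ``ct_input_1..3`` columns (and optionally a ``dilution`` column)."""
    out = df.copy()
    ratios = []
    for _, row in df.iterrows():
        d = dilution if dilution is not None else float(row.get("dilution", 1.0 / 500.0))
        rec = QpcrRecord(
            region=str(row.get("region", "?")),
            ct_ip=tuple(row[c] for c in df.columns if c.startswith("ct_ip_")),
            ct_input=tuple(row[c] for c in df.columns if c.startswith("ct_input_")),
            dilution=d,
        )
        ratios.append(qpcr_ratio(rec))
    out["ip_input_ratio"] = ratios
    return out


# ---------------------------------------------------------------------------
# TurboID / iBAQ
# ---------------------------------------------------------------------------

def ibaq_normalize(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Divide each purification column by the median of its nonzero values.

    Zeros remain zero (they are absent proteins, not small intensities);
    missing values stay missing. After normalization the median of the
    nonzero values is exactly 1.
    """
    out = table.copy()
    for col in columns:
        vals = out[col]
        nonzero = vals[(vals > 0) & vals.notna()]
        if nonzero.empty:
            raise ValueError(f"purification {col!r} has no nonzero iBAQ values")
        out[col] = vals / float(nonzero.median())
    return out


def impute_control(
    table: pd.DataFrame,
    control_col: str,
    seed: int,
    shift: float = 1.8,
    width: float = 0.3,
) -> pd.DataFrame:
    """Impute missing control-purification values from a down-shifted
    normal in log2 space (Perseus convention: mean shifted down by
    ``shift`` SDs of the observed log2 distribution, width ``width`` SDs).

    Deterministic under ``seed``. Zero values count as missing: they mean
    the protein was not observed in the control.
    """
    out = table.copy()
    vals = out[control_col]
    missing = vals.isna() | (vals == 0)
    observed = np.log2(vals[~missing].astype(float))
    if observed.empty:
        raise ValueError(f"no observed values in control column {control_col!r}")
    mu, sd = float(observed.mean()), float(observed.std(ddof=1))
    if not math.isfinite(sd) or sd == 0:
        sd = 1.0  # degenerate one-point distribution; still down-shift
    rng = np.random.default_rng(seed)
    n = int(missing.sum())
    if n:
        draws = rng.normal(mu - shift * sd, width * sd, size=n)
        out.loc[missing, control_col] = 2.0 ** draws
    return out


def log2_enrichment(table: pd.DataFrame, bait_col: str, control_col: str) -> pd.Series:
    """Per-protein ``log2(bait) - log2(control)`` on a normalized, imputed
    table; zero or missing bait gives NaN (protein absent from bait)."""
    bait = table[bait_col].astype(float)
    control = table[control_col].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.log2(bait) - np.log2(control)
    enr[(bait <= 0) | bait.isna()] = np.nan
    n_na = int(enr.isna().sum())
    if n_na:
        logger.warning("log2_enrichment: %d proteins without defined enrichment", n_na)
    return pd.Series(enr, index=table.index, name="log2_enrichment")


def welch_test(x, y) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch test needs >= 2 values per group")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def category_test(
    enrichments: pd.Series,
    categories: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category summaries and pairwise Welch tests of log2 enrichments.

    Returns ``(summary, tests)``: one summary row per category (n, mean,
    median, quartiles) and one test row per category pair (Welch t, p,
    stars). Defaults to all category pairs in first-appearance order.
    """
    df = pd.DataFrame({"enrichment": enrichments, "category": categories}).dropna(subset=["enrichment"])
    cats = list(dict.fromkeys(df["category"]))
    summary = (
        df.groupby("category", sort=False)["enrichment"]
        .agg(n="count", mean="mean", median="median",
             q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
        .reset_index()
    )
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cats) for b in cats[i + 1 :]]
    rows = []
    for a, b in pairs:
        t, p = welch_test(df.loc[df["category"] == a, "enrichment"], df.loc[df["category"] == b, "enrichment"])
        rows.append({"category_a": a, "category_b": b, "t": t, "pvalue": p, "stars": significance_stars(p)})
    return summary, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# microscopy ROI statistics
# ---------------------------------------------------------------------------

@dataclass
class RoiStats:
    max: float
    log10_max: float
    max_over_avg: float
    region_ratio: float | None = None  # mean(region1) / mean(region2)


def roi_stats(intensities, second_region=None) -> RoiStats:
    """Focal-signal statistics of one region of interest.

    ``max_over_avg`` (maximum intensity over average intensity) is the
    condensation readout: 1 for a flat region, larger when the signal
    concentrates in a focus. When a second region (e.g. nucleoplasm) is
    given, the mean-intensity ratio region1/region2 is also computed.
    """
    v = np.asarray(intensities, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty region of interest")
    if np.any(v < 0):
        raise ValueError("intensities must be non-negative")
    vmax = float(v.max())
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("zero mean intensity in region of interest")
    ratio = None
    if second_region is not None:
        w = np.asarray(second_region, dtype=float)
        w = w[np.isfinite(w)]
        if w.size == 0:
            raise ValueError("empty second region")
        wmean = float(w.mean())
        if wmean == 0:
            raise ValueError("zero mean intensity in second region")
        ratio = mean / wmean
    return RoiStats(
        max=vmax,
        log10_max=math.log10(vmax) if vmax > 0 else -math.inf,
        max_over_avg=vmax / mean,
        region_ratio=ratio,
    )
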