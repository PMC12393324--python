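"""Formula-level companion analyses: ΔF/F₀, DE-table filtering, and π.

These small computations accompany the behavioral pipeline:

* :func:`delta_f_over_f` normalizes a fluorescence trace against the mean of
  a pre-stimulus baseline window (20 frames by default):
  ΔF/F₀ = (F_t − F₀)/F₀.
* :func:`count_significant` applies the significance filter used on the
  foreleg differential-expression table (|log-fold change| > 1 and adjusted
  p < 0.05); the packaged 82-row table is available via
  :func:`load_foreleg_de_table`.
* :func:`variant_site_filter` and :func:`pairwise_pi` reproduce the
  transcriptome diversity computation on already-called site tables:
  hard site filters (mapping quality > 40, strand bias < 50, strand odds
  ratio < 4, per-allele coverage > 10, quality-by-depth < 1.5 — the
  comparator of the last filter is configurable, see the docstring), a
  15x-coverage and 95%-call-rate screen, then
  π = variant sites / all retained sites per transcript and pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "delta_f_over_f",
    "load_foreleg_de_table",
    "count_significant",
    "variant_site_filter",
    "pairwise_pi",
    "PiResult",
]

DE_TABLE_COLUMNS = ["gene", "base_mean", "lfc", "padj", "direction"]


def delta_f_over_f(trace, baseline_frames: int = 20,
                   baseline_start: int = 0) -> np.ndarray:
    """Baseline-normalized fluorescence: (F_t − F₀)/F₀.

    F₀ is the mean of ``baseline_frames`` samples starting at
    ``baseline_start``, all of which must precede the stimulus (the caller's
    responsibility).  The full trace is normalized element-wise.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    stop = baseline_start + baseline_frames
    if baseline_start < 0 or stop > len(trace):
        raise ValueError(
            f"trace has {len(trace)} samples, cannot take baseline "
            f"[{baseline_start}, {stop})")
    f0 = trace[baseline_start:stop].mean()
    if f0 == 0:
        raise ValueError("baseline fluorescence F0 is zero")
    return (trace - f0) / f0


def load_foreleg_de_table() -> pd.DataFrame:
    """The packaged 82-row foreleg differential-expression table."""
    with resources.files("courtrack.data").joinpath(
            "table1_foreleg_de.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def count_significant(table: pd.DataFrame, lfc_abs_min: float = 1.0,
                      alpha: float = 0.05) -> int:
    """Rows with |log-fold change| strictly above ``lfc_abs_min`` and
    adjusted p-value strictly below ``alpha``."""
    if len(table) == 0:
        return 0
    return int(((table["lfc"].abs() > lfc_abs_min)
                & (table["padj"] < alpha)).sum())


SITE_METRICS = {
    "mapping_quality": ("gt", 40.0),
    "strand_bias": ("lt", 50.0),
    "strand_odds_ratio": ("lt", 4.0),
    "allele_depth": ("gt", 10.0),
    "qual_by_depth": ("lt", 1.5),
}


def variant_site_filter(raw: pd.DataFrame,
                        qd_upper_bound: bool = True) -> pd.DataFrame:
    """Hard-filter variant sites on the five quality metrics.

    All comparisons are strict, as printed: mapping_quality > 40,
    strand_bias < 50, strand_odds_ratio < 4, allele_depth > 10 and
    qual_by_depth < 1.5.  The quality-by-depth comparator is unusual — the
    conventional hard filter bounds QD from *below* — so
    ``qd_upper_bound=False`` flips that single comparison to
    qual_by_depth > 1.5.  Sites with any missing metric are dropped with a
    warning.
    """
    if len(raw) == 0:
        return raw.copy()
    missing_cols = [c for c in SITE_METRICS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"site table missing metric columns: {missing_cols}")
    metrics = raw[list(SITE_METRICS)]
    incomplete = metrics.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"dropping {int(incomplete.sum())} site(s) with "
                      "missing quality metrics", stacklevel=2)
    keep = ~incomplete
    for col, (op, thr) in SITE_METRICS.items():
        if col == "qual_by_depth" and not qd_upper_bound:
            op = "gt"
        vals = raw[col]
        keep &= (vals > thr) if op == "gt" else (vals < thr)
    return raw[keep.fillna(False)].copy()


@dataclass
class PiResult:
    """Pairwise nucleotide diversity for one strain pair.

    ``pooled`` divides total variant sites by total retained sites;
    ``transcript_mean`` averages the per-transcript values unweighted (both
    poolings are reported since either convention is defensible).
    """

    per_transcript: pd.DataFrame    # transcript, n_sites, n_variants, pi
    pooled: float
    transcript_mean: float


def pairwise_pi(sites: pd.DataFrame, strain_a: str, strain_b: str,
                min_cov: int = 15, min_call_rate: float = 0.95) -> PiResult:
    """π = variant sites / all retained sites for one strain pair.

    ``sites`` holds one row per (transcript, site) with per-strain columns
    ``cov_<strain>`` (read coverage; NaN or 0 when uncalled) and
    ``allele_<strain>`` (called base, NaN when uncalled).  Filtering:

    1. transcripts whose fraction of called sites falls below
       ``min_call_rate`` in *any* strain column present are excluded;
    2. of the remaining sites, only those with coverage >= ``min_cov`` in
       both members of the pair are retained;
    3. a retained site is a variant when the two called alleles differ.

    Raises if either strain is absent; returns NaN π values when no sites
    survive.
    """
    for s in (strain_a, strain_b):
        if f"cov_{s}" not in sites.columns or f"allele_{s}" not in sites.columns:
            raise ValueError(f"strain {s!r} not present in site table")
    strains = sorted(c[len("allele_"):] for c in sites.columns
                     if c.startswith("allele_"))

    # call-rate screen across all strains in the table
    called = pd.DataFrame(
        {s: sites[f"allele_{s}"].notna() for s in strains})
    called["transcript"] = sites["transcript"].to_numpy()
    rate = called.groupby("transcript").mean()
    ok_transcripts = rate.index[(rate >= min_call_rate).all(axis=1)]

    sub = sites[sites["transcript"].isin(ok_transcripts)]
    cov_ok = ((sub[f"cov_{strain_a}"].fillna(0) >= min_cov)
              & (sub[f"cov_{strain_b}"].fillna(0) >= min_cov)
              & sub[f"allele_{strain_a}"].notna()
              & sub[f"allele_{strain_b}"].notna())
    sub = sub[cov_ok]

    if len(sub) == 0:
        empty = pd.DataFrame(columns=["transcript", "n_sites",
                                      "n_variants", "pi"])
        return PiResult(empty, float("nan"), float("nan"))

    variant = (sub[f"allele_{strain_a}"] != sub[f"allele_{strain_b}"])
    per = (pd.DataFrame({"transcript": sub["transcript"],
                         "variant": variant.astype(int)})
           .groupby("transcript")
           .agg(n_sites=("variant", "size"), n_variants=("variant", "sum"))
           .reset_index())
    per["pi"] = per["n_variants"] / per["n_sites"]
    pooled = float(per["n_variants"].sum() / per["n_sites"].sum())
    return PiResult(per, pooled, float(per["pi"].mean()))
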