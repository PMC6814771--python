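"""Sex-chromosome aneuploidy calling from SNP-array intensity summaries.

A sample is summarised by its median log-R ratio (mLRR) over X markers and
over markers in the male-specific region of Y, the chromosome-1 LRR SD
(array quality), and the fraction of X markers with B-allele frequency near
0.5 (heterozygosity).  Calling proceeds per platform:

* quality screen: chr1 LRR SD above 0.28, or membership in an excluded
  genotyping batch, fails QC;
* X loss in EHR-documented females: X mLRR below the platform screen
  (HOEE -0.28, GSA -0.20) with chromosome-wide loss of heterozygosity is a
  45,X-class call; the mosaic fraction is the ratio of the sample mLRR to
  the platform's minimum complete-45,X mLRR, with >= 0.80 called 45,X
  (complete to nearly complete) and [0.60, 0.80) called 45,X/46,XX;
* low X mLRR with preserved heterozygosity is flagged ambiguous — the
  age-related mosaic-loss pattern, where a random X is lost per event, so
  BAF stays at expected heterozygous levels;
* gains: X mLRR above the gain threshold gives 47,XXX (no Y) or 47,XXY
  (Y present); Y mLRR above the gain threshold gives 47,XYY;
* signals inconsistent with the recorded sex (e.g. a female with Y
  material) are emitted as ambiguous, never force-fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

X45_CLASS = ("45,X", "45,X/46,XX")


@dataclass
class CallerThresholds:
    """Per-platform calling thresholds; only the loss screens are printed
    in the source material, the rest are configurable defaults."""

    loss_x: dict = field(default_factory=lambda: {"HOEE": -0.28, "GSA": -0.20})
    ref_min: dict = field(default_factory=lambda: {"HOEE": -0.47, "GSA": -0.34})
    gain_x: float = 0.10
    gain_y: float = 0.10
    baf_loh_max: float = 0.05
    y_absent_below: float = -0.50
    chr1_sd_max: float = 0.28
    complete_min: float = 0.80
    mosaic_min: float = 0.60


@dataclass
class KaryotypeCall:
    sample_id: str
    karyotype: str                 # one of the seven complements or "ambiguous"
    mosaic_fraction: float | None  # present only for the 45,X class
    qc_pass: bool
    reasons: list[str] = field(default_factory=list)


def compute_mlrr(per_marker_lrr, region_mask=None) -> float:
    """Median log-R ratio over the masked markers."""
    values = np.asarray(per_marker_lrr, dtype=float)
    if region_mask is not None:
        values = values[np.asarray(region_mask, dtype=bool)]
    if values.size == 0:
        raise ValueError("no markers in mask")
    return float(np.median(values))


def qc_filter(signal, excluded_batches=(), thresholds: CallerThresholds | None = None):
    """Array-quality screen. Fails iff chr1 LRR SD is strictly above the
    bound or the sample's genotyping batch is excluded."""
    t = thresholds or CallerThresholds()
    reasons = []
    if signal["chr1_lrr_sd"] > t.chr1_sd_max:
        reasons.append("chr1_lrr_sd_above_0.28")
    if signal["batch"] in set(excluded_batches):
        reasons.append("excluded_batch")
    return len(reasons) == 0, reasons


def estimate_mosaic_fraction(mlrr_x: float, platform: str,
                             thresholds: CallerThresholds | None = None) -> float:
    """45,X cell fraction: sample mLRR over the platform's minimum complete
    45,X mLRR, clipped below at zero."""
    t = thresholds or CallerThresholds()
    ref = t.ref_min[platform]
    if ref >= 0:
        raise ValueError("platform reference minimum must be negative")
    return max(0.0, mlrr_x / ref)


def call_karyotype(signal, thresholds: CallerThresholds | None = None,
                   excluded_batches=()) -> KaryotypeCall:
    """Call one sample's sex-chromosome complement.

    ``signal`` is a mapping with sample_id, platform, batch, ehr_sex,
    mlrr_x, mlrr_y, chr1_lrr_sd, baf_het_rate_x.
    """
    t = thresholds or CallerThresholds()
    sid = signal.get("sample_id", "")
    ok, reasons = qc_filter(signal, excluded_batches, t)
    if not ok:
        return KaryotypeCall(sid, "ambiguous", None, False, ["qc_fail"] + reasons)

    sex = signal["ehr_sex"]
    mx, my = signal["mlrr_x"], signal["mlrr_y"]
    y_present = my > t.y_absent_below

    if sex == "F" and y_present:
        return KaryotypeCall(sid, "ambiguous", None, True, ["sex_inconsistent_y_in_female"])
    if sex == "M" and not y_present:
        return KaryotypeCall(sid, "ambiguous", None, True, ["sex_inconsistent_no_y_in_male"])

    # gains first: they cannot be confused with the loss path
    if mx > t.gain_x:
        karyo = "47,XXY" if y_present else "47,XXX"
        return KaryotypeCall(sid, karyo, None, True, ["x_gain"])
    if y_present and my > t.gain_y:
        return KaryotypeCall(sid, "47,XYY", None, True, ["y_gain"])

    if sex == "F":
        if mx < t.loss_x[signal["platform"]]:
            if signal["baf_het_rate_x"] < t.baf_loh_max:
                frac = estimate_mosaic_fraction(mx, signal["platform"], t)
                if frac >= t.complete_min:
                    return KaryotypeCall(sid, "45,X", frac, True, ["x_loss_complete"])
                if frac >= t.mosaic_min:
                    return KaryotypeCall(sid, "45,X/46,XX", frac, True, ["x_loss_mosaic"])
                return KaryotypeCall(sid, "46,XX", None, True, ["ratio_below_0.60"])
            return KaryotypeCall(sid, "ambiguous", None, True,
                                 ["low_mlrr_with_preserved_heterozygosity"])
        return KaryotypeCall(sid, "46,XX", None, True, [])
    return KaryotypeCall(sid, "46,XY", None, True, [])


def call_cohort(signals: pd.DataFrame, thresholds: CallerThresholds | None = None,
                excluded_batches=()) -> pd.DataFrame:
    """Vectorized driver over a signal table; one KaryotypeCall row each."""
    calls = [call_karyotype(row, thresholds, excluded_batches)
             for row in signals.to_dict("records")]
    return pd.DataFrame({
        "sample_id": [c.sample_id for c in calls],
        "karyotype": [c.karyotype for c in calls],
        "mosaic_fraction": [np.nan if c.mosaic_fraction is None else c.mosaic_fraction
                            for c in calls],
        "qc_pass": [c.qc_pass for c in calls],
        "reasons": [";".join(c.reasons) for c in calls],
    })
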