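"""Extracted-volume estimation from the electrowetting current change.

The hold currents before and after extraction give the organic-barrel
resistance with and without the cytoplasm plug; inverting the two-segment
cone model yields the ingress length, and the frustum volume of that
column is the extracted-volume estimate.  The estimate is qualitative:
the cytoplasm conductivity is only known as a range (0.35-0.5 S/m), so
every estimate carries its assumptions and an uncertainty interval
obtained by re-evaluating at the two range endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phase_detect import ExtractionMeasurement
from .sicm_model import (
    DEFAULT_KAPPA_CYT,
    DEFAULT_KAPPA_ORG,
    InvalidParameterError,
    PipetteGeometry,
    invert_ingress,
    plug_volume,
)

__all__ = ["VolumeEstimate", "estimate_volume", "volume_cohort_summary"]

KAPPA_CYT_RANGE = (0.35, 0.5)


@dataclass
class VolumeEstimate:
    """Ingress length and extracted volume inferred from one measurement.

    ``volume_lo``/``volume_hi`` bracket the estimate over the cytoplasm
    conductivity range; ``assumptions`` records everything the estimate
    depends on.  ``zero_delta`` flags measurements with no current
    increase (volume reported as zero with a warning rather than raised).
    """

    ingress_length: float
    volume: float
    resistance_before: float
    resistance_after: float
    delta_i: float
    volume_lo: float = 0.0
    volume_hi: float = 0.0
    zero_delta: bool = False
    assumptions: dict = field(default_factory=dict)


def estimate_volume(
    measurement: ExtractionMeasurement,
    bias: float,
    geometry: PipetteGeometry,
    kappa_cyt: float = DEFAULT_KAPPA_CYT,
    kappa_org: float = DEFAULT_KAPPA_ORG,
    kappa_cyt_range: tuple = KAPPA_CYT_RANGE,
) -> VolumeEstimate:
    """Extracted-volume estimate from a Delta-i_org measurement.

    ``R_before = |bias| / |pre_hold|``, ``R_after = |bias| / |post_hold|``;
    the ingress length solves the plug-resistance model at ``R_after`` and
    the volume is the frustum of that length.  Monotone increasing in the
    current increase Delta-i.
    """
    pre, post = abs(measurement.pre_hold), abs(measurement.post_hold)
    if pre <= 0:
        raise InvalidParameterError("pre-extraction hold current must be non-zero")
    r_before = abs(bias) / pre
    assumptions = {
        "kappa_cyt": kappa_cyt,
        "kappa_org": kappa_org,
        "kappa_cyt_range": tuple(kappa_cyt_range),
        "r_tip_m": geometry.r_tip,
        "taper": geometry.taper,
        "length_m": geometry.length,
        "bias_v": bias,
    }
    if post <= pre:  # no measurable ingress
        return VolumeEstimate(
            ingress_length=0.0,
            volume=0.0,
            resistance_before=r_before,
            resistance_after=r_before if post == 0 else abs(bias) / post,
            delta_i=post - pre,
            zero_delta=True,
            assumptions=assumptions,
        )
    r_after = abs(bias) / post
    ell = invert_ingress(r_after, geometry, kappa_cyt, kappa_org)
    lo, hi = sorted(
        plug_volume(invert_ingress(r_after, geometry, k, kappa_org), geometry)
        for k in kappa_cyt_range
    )
    return VolumeEstimate(
        ingress_length=ell,
        volume=plug_volume(ell, geometry),
        resistance_before=r_before,
        resistance_after=r_after,
        delta_i=post - pre,
        volume_lo=lo,
        volume_hi=hi,
        assumptions=assumptions,
    )


def volume_cohort_summary(estimates: list, volume_threshold_fl: float = 200.0) -> dict:
    """Order statistics of a cohort of volume estimates.

    Returns the median and quartiles of Delta-i and of the volume, and the
    fraction of estimates at or below ``volume_threshold_fl``.
    """
    if not estimates:
        raise InvalidParameterError("cohort summary requires at least one estimate")
    delta = np.array([e.delta_i for e in estimates])
    vols = np.array([e.volume for e in estimates])
    q1, q2, q3 = np.percentile(delta, [25, 50, 75])
    v1, v2, v3 = np.percentile(vols, [25, 50, 75])
    return {
        "n": len(estimates),
        "delta_i_median": float(q2),
        "delta_i_quartiles": (float(q1), float(q3)),
        "volume_median_fl": float(v2),
        "volume_quartiles_fl": (float(v1), float(v3)),
        "fraction_leq_threshold": float(np.mean(vols <= volume_threshold_fl)),
        "volume_threshold_fl": volume_threshold_fl,
    }
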