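"""Seeded generators emulating the study's inputs.

Two ingredients of the analysis are not shippable data: the literature
compilation of per-method T1 values and the in vivo quantitative-MT parameter
maps.  This module generates both from known ground truth so that every stage
of the pipeline (roster fit, model comparison, voxelwise replication) can be
exercised and validated end to end:

* :func:`generate_roster` — per-method T1 observations produced by running
  the full forward pipeline (MT simulation + method-specific mono fit) at a
  known parameter set and adding observation noise.  Gaussian noise matches
  the least-squares estimator's assumption; an optional heavy-tailed mode
  (Student-t, 3 degrees of freedom) probes outlier sensitivity.
* :func:`generate_qmt_maps` — smooth white-matter-like parameter maps
  (low-pass-filtered Gaussian fields around literature means), a blob-shaped
  white-matter mask and a smooth multiplicative transmit-field (B1) map.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .meta_analysis import QMTMaps, RosterObservation, predict_t1_roster
from .sequences import preset_names
from .spin_models import WM_3T_FIT, WM_3T_REFERENCE, TwoPoolParameters

__all__ = ["RosterSpec", "MapSpec", "generate_roster", "generate_qmt_maps"]


@dataclass(frozen=True)
class RosterSpec:
    """Specification of a synthetic literature roster.

    ``noise_sd`` is the per-method observation noise in seconds (default
    0.02 s, a ~2% scatter on white-matter T1); the default protocol roster is
    the full 25-method preset list and the default truth is the fitted
    white-matter parameter set.
    """

    true_params: TwoPoolParameters = WM_3T_FIT
    roster: tuple = field(default_factory=lambda: tuple(preset_names()))
    model: str = "generalized_bloch"
    noise_sd: float = 0.02
    seed: int = 0
    heavy_tailed: bool = False

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_roster(spec: RosterSpec) -> list:
    """Draw one synthetic roster: forward predictions at the true parameters
    plus noise, truncated to positive values (resampled if non-positive)."""
    pred, errors = predict_t1_roster(
        spec.true_params, list(spec.roster), spec.model
    )
    bad = [f"{m}: {e}" for m, e in zip(spec.roster, errors) if e]
    if np.any(~np.isfinite(pred)):
        raise RuntimeError("forward prediction failed for: " + "; ".join(bad))
    rng = np.random.default_rng(spec.seed)
    out = []
    for method_id, t in zip(spec.roster, pred):
        obs = -1.0
        while obs <= 0:
            if spec.noise_sd == 0:
                obs = t
                break
            if spec.heavy_tailed:
                obs = t + spec.noise_sd * rng.standard_t(3)
            else:
                obs = t + spec.noise_sd * rng.standard_normal()
        out.append(
            RosterObservation(method_id, float(obs), f"synthetic(seed={spec.seed})")
        )
    return out


@dataclass(frozen=True)
class MapSpec:
    """Specification of synthetic white-matter-like qMT maps.

    Means default to reference quantitative-MT literature values for white
    matter at 3 T; standard deviations are modest tissue-scale variations,
    spatially smoothed (Gaussian kernel, ``smooth_sigma`` voxels).  The
    transmit field is a smooth multiplicative map within ``b1_range``.
    """

    shape: tuple = (32, 32)
    means: dict = field(
        default_factory=lambda: {
            "m0s": WM_3T_REFERENCE.m0s,
            "t1f": WM_3T_REFERENCE.t1f,
            "t1s": WM_3T_REFERENCE.t1s,
            "t2f": WM_3T_REFERENCE.t2f,
            "t2s": WM_3T_REFERENCE.t2s,
            "rx": WM_3T_REFERENCE.rx,
            "pd": 1.0,
        }
    )
    sds: dict = field(
        default_factory=lambda: {
            "m0s": 0.02,
            "t1f": 0.12,
            "t1s": 0.03,
            "t2f": 5e-3,
            "t2s": 0.8e-6,
            "rx": 1.2,
            "pd": 0.05,
        }
    )
    smooth_sigma: float = 3.0
    b1_range: tuple = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 4:
            raise ValueError("grid too small")


_CLIP = {
    "m0s": (0.005, 0.6),
    "t1f": (0.2, 8.0),
    "t1s": (0.05, 2.0),
    "t2f": (20e-3, 0.3),
    "t2s": (5e-6, 30e-6),
    "rx": (1.0, 100.0),
    "pd": (0.1, 3.0),
}


def _smooth_field(rng, shape, sigma):
    """Zero-mean, unit-sample-sd smooth field, truncated at +-3 so that the
    per-parameter priors bound every voxel by construction."""
    w = rng.standard_normal(shape)
    f = gaussian_filter(w, sigma, mode="wrap")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return np.clip(f, -3.0, 3.0)


def generate_qmt_maps(spec: MapSpec) -> QMTMaps:
    """Generate smooth random parameter maps, a blob-shaped white-matter mask
    and a smooth B1 map; reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    fields = {}
    for name in ("m0s", "t1f", "t1s", "t2f", "t2s", "rx", "pd"):
        f = spec.means[name] + spec.sds[name] * _smooth_field(
            rng, spec.shape, spec.smooth_sigma
        )
        fields[name] = np.clip(f, *_CLIP[name])
    lo, hi = spec.b1_range
    b1 = 0.5 * (lo + hi) + 0.5 * (hi - lo) * np.clip(
        _smooth_field(rng, spec.shape, max(spec.smooth_sigma * 2, 4.0)) / 2.0,
        -1.0,
        1.0,
    )
    # blob-shaped mask: central ellipse modulated by smoothed noise
    yy, xx = np.indices(spec.shape)
    cy, cx = (np.asarray(spec.shape) - 1) / 2.0
    ry, rx_ = spec.shape[0] * 0.33, spec.shape[1] * 0.33
    ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx_) ** 2
    wobble = 0.35 * _smooth_field(rng, spec.shape, spec.smooth_sigma)
    mask = ellipse + wobble < 1.0
    if not mask.any():  # degenerate wobble draw: fall back to the ellipse
        mask = ellipse < 1.0
    return QMTMaps(
        m0s=fields["m0s"],
        t1f=fields["t1f"],
        t1s=fields["t1s"],
        t2f=fields["t2f"],
        t2s=fields["t2s"],
        rx=fields["rx"],
        pd=fields["pd"],
        b1=b1,
        mask=mask,
    )
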