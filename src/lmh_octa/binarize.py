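"""En-face angiogram binarization: vessel maps and perfusion maps.

The vessel map fuses three operators on the normalized image — a global
intensity band (white pixels, ratio 0.7-1.0), a multiscale Hessian
(Frangi) vesselness filter, and a local-mean adaptive threshold — followed
by small-speckle removal.  The fusion rule is

    vessel  =  global  OR  (adaptive AND vesselness >= cut)

so the global band preserves large bright vessels while the AND branch
admits faint capillaries only where both the local contrast and the
ridge-likeness agree.  Perfused vessels are vessel pixels whose
frame-to-frame decorrelation

    D = 1 - mean_t [ 2 f_t f_{t+1} / (f_t^2 + f_{t+1}^2) ]

exceeds a threshold; static structure has D = 0, moving blood fluctuates
across repeated frames and decorrelates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import frangi
from skimage.morphology import remove_small_objects

__all__ = [
    "EnFaceAngiogram",
    "BinaryVesselMap",
    "PerfusionMap",
    "BinarizationParams",
    "normalize_image",
    "global_threshold",
    "hessian_vesselness",
    "adaptive_threshold",
    "fuse_vessel_map",
    "decorrelation_map",
    "perfusion_map",
    "binarize_angiogram",
]

#: lower bound of the white-pixel intensity band on the normalized image
GLOBAL_BAND_LOW = 0.7


@dataclass
class EnFaceAngiogram:
    """Calibrated en-face angiogram for one capillary plexus.

    ``image`` is the averaged/en-face intensity in [0, 1]; ``frames`` is
    the optional repeated-acquisition stack used for decorrelation.  The
    plexus label (SCP/DCP) is carried through unchanged — slab segmentation
    happens upstream on the device.  ``quality`` is the device Q score,
    a pass-through field.
    """

    image: np.ndarray
    pixel_pitch_um: float
    plexus: str = "SCP"
    frames: np.ndarray | None = None
    quality: float | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image must be normalized to [0, 1]")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.plexus not in ("SCP", "DCP"):
            raise ValueError("plexus must be 'SCP' or 'DCP'")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=float)
            if self.frames.ndim != 3 or self.frames.shape[1:] != self.image.shape:
                raise ValueError("frames must be a stack matching the image shape")


@dataclass
class BinaryVesselMap:
    mask: np.ndarray
    pixel_pitch_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PerfusionMap:
    mask: np.ndarray
    decorrelation: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != np.asarray(self.decorrelation).shape:
            raise ValueError("mask and decorrelation shapes differ")


@dataclass
class BinarizationParams:
    """Tunable parameters of the vessel/perfusion segmentation."""

    global_cut: float = GLOBAL_BAND_LOW
    scales_px: tuple[float, ...] = (1.0, 2.0, 3.0)
    frangi_beta: float = 0.5
    adaptive_window_px: int = 15
    adaptive_offset: float = 0.02
    vesselness_cut: float = 0.05
    tau_d: float = 0.05
    min_object_px: int = 5
    #: apply the 0.7 white-pixel band to the fused map instead of OR-ing it
    band_after_fusion: bool = False


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1]; constant images map to zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty image")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("constant image: normalization degenerates to zeros", stacklevel=2)
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def global_threshold(img: np.ndarray, low: float = GLOBAL_BAND_LOW) -> np.ndarray:
    """White-pixel band on the normalized image: true iff intensity >= low."""
    return np.asarray(img, dtype=float) >= low


def hessian_vesselness(img: np.ndarray, scales_px=(1.0, 2.0, 3.0), beta: float = 0.5) -> np.ndarray:
    """Multiscale Frangi vesselness for bright ridges, rescaled to [0, 1].

    Gaussian-derivative Hessian eigenvalues at each scale; the response is
    high where the smaller eigenvalue is near zero and the larger one is
    strongly negative (a bright line on a dark background), and the
    maximum over scales is taken.
    """
    img = np.asarray(img, dtype=float)
    scales = tuple(float(s) for s in scales_px)
    if not scales:
        raise ValueError("need at least one scale")
    if max(scales) > min(img.shape) / 4:
        raise ValueError("scale exceeds a quarter of the image size")
    v = frangi(img, sigmas=scales, beta=beta, black_ridges=False, mode="reflect")
    peak = v.max()
    return v / peak if peak > 0 else v


def adaptive_threshold(img: np.ndarray, window_px: int = 15, offset: float = 0.02) -> np.ndarray:
    """True iff intensity exceeds the local mean by more than ``offset``.

    The local mean is taken over an odd square window with reflective
    padding.  A positive offset suppresses flat regions entirely (a
    constant image yields no pixels), which is what the operator is for:
    thin vessels rise far above their neighborhood mean, background does
    not.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    img = np.asarray(img, dtype=float)
    local_mean = uniform_filter(img, size=window_px, mode="reflect")
    return img > local_mean + offset


def fuse_vessel_map(
    global_mask: np.ndarray,
    vesselness: np.ndarray,
    adaptive_mask: np.ndarray,
    vesselness_cut: float = 0.05,
    pixel_pitch_um: float = 5.7,
    min_object_px: int = 5,
) -> BinaryVesselMap:
    """Combine the three operators into the binary vessel map.

    vessel = global OR (adaptive AND vesselness >= cut), then connected
    components smaller than ``min_object_px`` pixels (4-connectivity) are
    removed as speckle.
    """
    g = np.asarray(global_mask, dtype=bool)
    a = np.asarray(adaptive_mask, dtype=bool)
    v = np.asarray(vesselness, dtype=float)
    if not (g.shape == a.shape == v.shape):
        raise ValueError("operator outputs have mismatched shapes")
    fused = g | (a & (v >= vesselness_cut))
    if min_object_px > 1:
        # components strictly smaller than min_object_px are speckle
        fused = remove_small_objects(fused, max_size=min_object_px - 1, connectivity=1)
    return BinaryVesselMap(
        mask=fused,
        pixel_pitch_um=pixel_pitch_um,
        provenance={
            "vesselness_cut": vesselness_cut,
            "min_object_px": min_object_px,
            "rule": "global OR (adaptive AND vesselness>=cut)",
        },
    )


def decorrelation_map(frames: np.ndarray) -> np.ndarray:
    """Per-pixel decorrelation over consecutive frame pairs, in [0, 1].

    For each pair, ``d = 1 - 2 f_t f_{t+1} / (f_t^2 + f_{t+1}^2)``; pairs
    where both frames are zero contribute 0 (no signal, no decorrelation).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")
    f0 = frames[:-1]
    f1 = frames[1:]
    den = f0**2 + f1**2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, 1.0 - 2.0 * f0 * f1 / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(d.mean(axis=0), 0.0, 1.0)


def perfusion_map(vessels: BinaryVesselMap, decorr: np.ndarray, tau_d: float = 0.05) -> PerfusionMap:
    """Perfused vessels: vessel pixels with decorrelation >= tau_d."""
    if not 0 <= tau_d <= 1:
        raise ValueError("tau_d must lie in [0, 1]")
    decorr = np.asarray(decorr, dtype=float)
    if decorr.shape != vessels.mask.shape:
        raise ValueError("decorrelation map shape differs from vessel map")
    return PerfusionMap(mask=vessels.mask & (decorr >= tau_d), decorrelation=decorr)


def binarize_angiogram(
    angio: EnFaceAngiogram, params: BinarizationParams | None = None
) -> tuple[BinaryVesselMap, PerfusionMap | None]:
    """Full segmentation of one angiogram.

    Returns the vessel map and, when a frame stack is present, the
    perfusion map.  Without frames the perfusion map is ``None`` — PD is
    refused rather than silently equated to VD.
    """
    p = params or BinarizationParams()
    img = angio.image
    g = global_threshold(img, p.global_cut)
    v = hessian_vesselness(img, p.scales_px, p.frangi_beta)
    a = adaptive_threshold(img, p.adaptive_window_px, p.adaptive_offset)
    if p.band_after_fusion:
        # alternative reading: the 0.7 band gates the fused map instead
        fused = fuse_vessel_map(
            np.zeros_like(g), v, a, p.vesselness_cut, angio.pixel_pitch_um, 1
        ).mask
        mask = remove_small_objects(fused & g, max_size=p.min_object_px - 1, connectivity=1)
        vessels = BinaryVesselMap(
            mask=mask,
            pixel_pitch_um=angio.pixel_pitch_um,
            provenance={"rule": "(adaptive AND vesselness) AND global-band",
                        "vesselness_cut": p.vesselness_cut,
                        "min_object_px": p.min_object_px},
        )
    else:
        vessels = fuse_vessel_map(
            g, v, a, p.vesselness_cut, angio.pixel_pitch_um, p.min_object_px
        )
    vessels.provenance.update(
        {"global_cut": p.global_cut, "scales_px": list(p.scales_px),
         "frangi_beta": p.frangi_beta, "adaptive_window_px": p.adaptive_window_px,
         "adaptive_offset": p.adaptive_offset, "tau_d": p.tau_d,
         "band_after_fusion": p.band_after_fusion, "plexus": angio.plexus}
    )
    if angio.frames is None:
        return vessels, None
    decorr = decorrelation_map(angio.frames)
    return vessels, perfusion_map(vessels, decorr, p.tau_d)
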