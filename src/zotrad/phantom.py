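"""Synthetic two-phase CT phantoms with ground-truth lesion geometry.

The generator emulates the imaging situation the pipeline was designed for:
a roughly elliptical hyper-enhancing lesion (equivalent diameter <= 3 cm at
1 mm/px) sitting in homogeneous parenchyma, with

* a graded (sigmoidal) rim between lesion core and background whose width is
  the ground-truth zone of transition (ZOT);
* phase-dependent core contrast (arterial hyper-enhancement, venous washout);
* class-dependent texture heterogeneity: MVI+ lesions carry stronger
  stationary texture in both core and rim than MVI- lesions;
* a "manual-style" imperfect input mask, obtained by perturbing the true
  boundary radius with a low-frequency sinusoid of amplitude <= rim_width/2.

The rim width is parameterised so that the full width at half maximum of the
radial intensity derivative equals ``rim_width`` pixels, which makes the
ground truth directly recoverable by radial profiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .data import LabelledDataset
from .io import PhaseImage, RoiMask

#: FWHM of the derivative of the logistic function, in units of its scale k:
#: solving f'(t) = f'(0)/2 gives t = ±ln(3 + 2*sqrt(2)).
_LOGISTIC_DFWHM = 2.0 * math.log(3.0 + 2.0 * math.sqrt(2.0))

MVI_POS = "MVI+"
MVI_NEG = "MVI-"


@dataclass
class PhantomSpec:
    """Full parameterisation of one synthetic two-phase lesion."""

    image_shape: tuple[int, int] = (96, 96)
    spacing: tuple[float, float] = (1.0, 1.0)      # mm / pixel
    lesion_center: tuple[float, float] | None = None
    lesion_radii: tuple[float, float] = (14.0, 11.0)   # px semi-axes
    rim_width: float = 6.0                          # px, ground-truth ZOT width
    core_intensity_arterial: float = 110.0          # HU-like
    core_intensity_venous: float = 90.0
    background_intensity: float = 60.0
    texture_sd_core: float = 8.0                    # HU-like heterogeneity
    texture_sd_rim: float = 10.0
    texture_corr_len: float = 2.0                   # px
    noise_sd: float = 3.0
    label: str = MVI_NEG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_center is None:
            self.lesion_center = tuple((s - 1) / 2.0 for s in self.image_shape)
        if self.rim_width < 1:
            raise ValueError("rim_width must be >= 1 px")
        for name in ("texture_sd_core", "texture_sd_rim", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.label not in (MVI_POS, MVI_NEG):
            raise ValueError(f"label must be {MVI_POS!r} or {MVI_NEG!r}")
        # lesion must fit inside the image with margin >= rim_width
        for axis in range(2):
            c = self.lesion_center[axis]
            r = max(self.lesion_radii)
            if c - r - self.rim_width < 0 or c + r + self.rim_width > self.image_shape[axis] - 1:
                raise ValueError(
                    "lesion (radius %.1f px + rim %.1f px) does not fit inside "
                    "image of shape %s with the required margin"
                    % (r, self.rim_width, self.image_shape)
                )

    @property
    def label_binary(self) -> int:
        return 1 if self.label == MVI_POS else 0


def _lesion_geometry(spec: PhantomSpec):
    """Signed pixel distance to the ellipse boundary (positive inside)."""
    yy, xx = np.indices(spec.image_shape, dtype=float)
    cy, cx = spec.lesion_center
    a, b = spec.lesion_radii  # semi-axes along rows, columns
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    # ellipse radius along the direction of each pixel
    r_dir = 1.0 / np.sqrt((np.sin(theta) / a) ** 2 + (np.cos(theta) / b) ** 2)
    dist = np.hypot(dy, dx)
    return r_dir - dist, r_dir, theta, dist


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns
    -------
    (arterial, venous, manual_mask)
        Two :class:`PhaseImage` and the imperfect manual :class:`RoiMask`.
    """
    rng = np.random.default_rng(spec.seed)
    signed, r_dir, theta, dist = _lesion_geometry(spec)

    k = spec.rim_width / _LOGISTIC_DFWHM       # logistic scale
    w_in = expit(signed / k)                   # 1 in core, 0 in background
    w_rim = 4.0 * w_in * (1.0 - w_in)          # bump peaking at the border

    # stationary texture: white noise smoothed at the correlation length,
    # shared between phases (same underlying tissue structure)
    raw = rng.standard_normal(spec.image_shape)
    if spec.texture_corr_len > 0:
        raw = gaussian_filter(raw, spec.texture_corr_len)
    sd = raw.std()
    texture = raw / sd if sd > 0 else raw
    amplitude = spec.texture_sd_core * w_in + spec.texture_sd_rim * w_rim
    structured = amplitude * texture

    bg = spec.background_intensity
    imgs = {}
    for phase, core in (
        ("arterial", spec.core_intensity_arterial),
        ("venous", spec.core_intensity_venous),
    ):
        noise = spec.noise_sd * rng.standard_normal(spec.image_shape)
        vox = bg + (core - bg) * w_in + structured + noise
        imgs[phase] = PhaseImage(vox, spec.spacing, phase,
                                 subject_id=f"phantom-{spec.seed}")

    # manual-style mask: true support with sinusoidal boundary jitter
    n_lobes = int(rng.integers(3, 7))
    phase0 = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.2, 0.5) * spec.rim_width  # <= rim_width / 2
    jitter = amp * np.sin(n_lobes * theta + phase0)
    manual = dist <= (r_dir + jitter)
    mask = RoiMask(manual, kind="manual")
    return imgs["arterial"], imgs["venous"], mask


def true_rim_band(spec: PhantomSpec):
    """Ground-truth ZOT annulus: |signed distance| <= rim_width / 2."""
    signed = _lesion_geometry(spec)[0]
    return np.abs(signed) <= spec.rim_width / 2.0


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: class-conditional texture defaults: MVI+ lesions are more heterogeneous
#: in both the core and the transition zone than MVI- lesions.
DEFAULT_POS_PARAMS = dict(texture_sd_core=18.0, texture_sd_rim=22.0)
DEFAULT_NEG_PARAMS = dict(texture_sd_core=8.0, texture_sd_rim=10.0)

#: anatomical jitter applied per phantom (uniform half-ranges)
DEFAULT_JITTER = dict(
    lesion_radius=2.5,       # px, on each semi-axis
    rim_width=2.0,           # px
    core_intensity=8.0,      # HU
    background_intensity=5.0,
)


@dataclass
class CohortSpec:
    """Sampling plan for a cohort of labelled phantoms."""

    n_pos: int = 32
    n_neg: int = 57
    base: PhantomSpec = field(default_factory=PhantomSpec)
    pos_params: dict = field(default_factory=lambda: dict(DEFAULT_POS_PARAMS))
    neg_params: dict = field(default_factory=lambda: dict(DEFAULT_NEG_PARAMS))
    jitter: dict = field(default_factory=lambda: dict(DEFAULT_JITTER))
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")


@dataclass
class PhantomCase:
    """One generated cohort member."""

    subject_id: str
    label: str
    spec: PhantomSpec
    arterial: PhaseImage
    venous: PhaseImage
    manual_mask: RoiMask

    @property
    def label_binary(self) -> int:
        return 1 if self.label == MVI_POS else 0


def _draw_spec(base: PhantomSpec, class_params: dict, jitter: dict,
               label: str, seed: int, rng: np.random.Generator) -> PhantomSpec:
    jr = jitter.get("lesion_radius", 0.0)
    jw = jitter.get("rim_width", 0.0)
    jc = jitter.get("core_intensity", 0.0)
    jb = jitter.get("background_intensity", 0.0)
    radii = tuple(max(4.0, r + rng.uniform(-jr, jr)) for r in base.lesion_radii)
    rim = max(1.0, base.rim_width + rng.uniform(-jw, jw))
    kwargs = dict(
        lesion_radii=radii,
        rim_width=rim,
        core_intensity_arterial=base.core_intensity_arterial + rng.uniform(-jc, jc),
        core_intensity_venous=base.core_intensity_venous + rng.uniform(-jc, jc),
        background_intensity=base.background_intensity + rng.uniform(-jb, jb),
        label=label,
        seed=int(seed),
    )
    kwargs.update(class_params)
    return replace(base, **kwargs)


def generate_cohort(spec: CohortSpec) -> list[PhantomCase]:
    """Draw exactly ``n_pos`` MVI+ and ``n_neg`` MVI- phantoms.

    Per-phantom seeds derive deterministically from ``master_seed``, so the
    same cohort spec always yields bit-identical images.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    n_total = spec.n_pos + spec.n_neg
    child_seeds = ss.generate_state(n_total) % np.uint32(2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cases = []
    labels = [MVI_POS] * spec.n_pos + [MVI_NEG] * spec.n_neg
    for i, label in enumerate(labels):
        params = spec.pos_params if label == MVI_POS else spec.neg_params
        pspec = _draw_spec(spec.base, params, spec.jitter, label,
                           child_seeds[i], rng)
        arterial, venous, mask = generate_phantom(pspec)
        sid = f"{'pos' if label == MVI_POS else 'neg'}-{i:03d}"
        arterial.subject_id = venous.subject_id = sid
        cases.append(PhantomCase(sid, label, pspec, arterial, venous, mask))
    return cases


# ---------------------------------------------------------------------------
# image-free feature-table fixture
# ---------------------------------------------------------------------------

def generate_feature_table(n_pos: int, n_neg: int, n_features: int = 20,
                           n_informative: int = 2, effect_size: float = 2.0,
                           seed: int = 0) -> LabelledDataset:
    """Gaussian feature table with a planted class-mean shift.

    The first ``n_informative`` columns separate the classes by
    ``effect_size`` standard deviations; the remaining columns are pure
    noise.  Used to exercise selection / oversampling / classification
    without rendering images.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class counts must be >= 1")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = rng.standard_normal((n, n_features))
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    X[y == 1, :n_informative] += effect_size
    cols = [f"feat_{i:03d}" for i in range(n_features)]
    ids = [f"{'pos' if lab else 'neg'}-{i:03d}" for i, lab in enumerate(y)]
    return LabelledDataset(pd.DataFrame(X, columns=cols), y, ids)
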