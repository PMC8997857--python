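"""The 654-entry first-order radiomic feature catalogue.

Per contrast phase (A = arterial, V = venous) the catalogue contains

* 7 local first-order features x 12 global descriptors on the grey-level
  image within the tumour ROI                                   ->  84
* 10 local first-order features x 12 global descriptors on the gradient
  magnitude image within the ZOT                                -> 120
* 12 global descriptors directly on the ZOT gradient magnitudes ->  12

giving 2 x (84 + 120 + 12) = 432, plus the arterial/venous ratio of every
tumour (84) and ZOT (132) per-phase feature -> 216, plus 6 size features
(tumour voxels and ZOT pixels per phase and their A/V ratios): 654 total.

Local features are computed over the (2r+1)^2 pixel neighbourhood
intersected with the ROI ("parametric maps"); a neighbourhood needs at
least 4 pixels to contribute.  Names render canonically as
``"<LOCAL>-<descriptor> [<region>,<phase>]"``, e.g. ``"S-s [ZOT,A]"`` for
the skewness (descriptor) of the local-skewness map (local feature) of the
arterial-phase ZOT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import PhaseImage, RoiMask
from .zot import compute_gradient_field

logger = logging.getLogger(__name__)

#: local first-order feature codes (uppercase)
#: M mean, V variance, S skewness, K kurtosis, E entropy, U uniformity,
#: D median; ZOT maps additionally use R range, A mean absolute deviation,
#: Q root-mean-square.
TUMOUR_LOCALS = ("M", "V", "S", "K", "E", "U", "D")
ZOT_LOCALS = TUMOUR_LOCALS + ("R", "A", "Q")

#: global descriptor codes (lowercase): mean, standard deviation, median,
#: interquartile range, minimum, maximum, range, skewness, kurtosis,
#: entropy, uniformity, 90th percentile.
DESCRIPTORS = ("m", "sd", "md", "iq", "mn", "mx", "r", "s", "k", "e", "u", "p90")

N_BINS_DEFAULT = 64


@dataclass
class FeatureConfig:
    window_radius: int = 2
    n_bins: int = N_BINS_DEFAULT
    smoothing_sigma: float = 1.0        # for ZOT gradient-magnitude images
    ratio_epsilon: float = 1e-9
    tumour_locals: tuple = TUMOUR_LOCALS
    zot_locals: tuple = ZOT_LOCALS
    descriptors: tuple = DESCRIPTORS


@dataclass(frozen=True)
class FeatureName:
    """Structured feature identifier with canonical rendering."""

    local_code: str       # one of the local codes, or "GLOBAL" or "SIZE"
    descriptor_code: str  # one of the descriptor codes, or "" for SIZE
    region: str           # "T" or "ZOT"
    phase: str            # "A", "V" or "A/V"

    def render(self) -> str:
        if self.local_code == "SIZE":
            return f"SIZE [{self.region},{self.phase}]"
        return f"{self.local_code}-{self.descriptor_code} [{self.region},{self.phase}]"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass
class FeatureVector:
    """The named feature catalogue for one nodule."""

    values: dict
    subject_id: str = ""
    label: int | None = None
    n_missing: int = field(default=0)

    def __len__(self) -> int:
        return len(self.values)

    def family_counts(self) -> dict:
        """Feature counts per family (used to assert catalogue bookkeeping)."""
        counts = {"tumour_local_A": 0, "tumour_local_V": 0,
                  "zot_local_A": 0, "zot_local_V": 0,
                  "zot_global_A": 0, "zot_global_V": 0,
                  "ratio": 0, "size": 0}
        for name in self.values:
            region, phase = name[name.index("[") + 1:-1].split(",")
            if name.startswith("SIZE"):
                counts["size"] += 1
            elif phase == "A/V":
                counts["ratio"] += 1
            elif name.startswith("GLOBAL"):
                counts[f"zot_global_{phase}"] += 1
            elif region == "T":
                counts[f"tumour_local_{phase}"] += 1
            else:
                counts[f"zot_local_{phase}"] += 1
        return counts


# ---------------------------------------------------------------------------
# histogram helpers
# ---------------------------------------------------------------------------

def _bin_indices(values: np.ndarray, lo: float, hi: float, n_bins: int):
    """Equal-width bin index of each value over [lo, hi]; single bin if lo==hi."""
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _entropy_uniformity(p: np.ndarray):
    """Shannon entropy (bits) and uniformity (energy) of histogram masses."""
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((nz ** 2).sum())
    return entropy, uniformity


# ---------------------------------------------------------------------------
# local parametric maps
# ---------------------------------------------------------------------------

def _window_values(image: np.ndarray, mask: np.ndarray, radius: int):
    """Stack of masked neighbourhood values for every mask pixel.

    Returns (coords (n,2), vals (n, k*k) with NaN outside mask, counts (n,)).
    """
    k = 2 * radius + 1
    pv = np.pad(image.astype(float), radius, constant_values=np.nan)
    pm = np.pad(mask, radius, constant_values=False)
    wv = sliding_window_view(pv, (k, k))
    wm = sliding_window_view(pm, (k, k))
    coords = np.argwhere(mask)
    ys, xs = coords[:, 0], coords[:, 1]
    vals = wv[ys, xs].reshape(len(coords), -1).copy()
    valid = wm[ys, xs].reshape(len(coords), -1)
    vals[~valid] = np.nan
    counts = valid.sum(axis=1)
    return coords, vals, counts


def compute_local_maps(image: np.ndarray, mask: np.ndarray,
                       local_features: tuple, window_radius: int = 2,
                       n_bins: int = N_BINS_DEFAULT) -> dict:
    """All requested local parametric maps over the mask in one pass.

    Returns a dict ``code -> 1-D array`` of map values, aligned with the
    mask pixels in ``np.argwhere`` order; pixels whose neighbourhood holds
    fewer than 4 ROI pixels are excluded (from every map).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("mask is empty")
    coords, vals, counts = _window_values(image, mask, window_radius)
    ok = counts >= 4
    vals = vals[ok]
    counts = counts[ok].astype(float)
    n = len(vals)
    maps: dict[str, np.ndarray] = {}
    if n == 0:
        return {code: np.empty(0) for code in local_features}

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=1)
        dev = vals - mean[:, None]
        m2 = np.nanmean(dev ** 2, axis=1)
        if "M" in local_features:
            maps["M"] = mean
        if "V" in local_features:
            maps["V"] = m2
        if "S" in local_features or "K" in local_features:
            safe = np.where(m2 > 1e-24, m2, 1.0)
            m3 = np.nanmean(dev ** 3, axis=1)
            m4 = np.nanmean(dev ** 4, axis=1)
            skew = np.where(m2 > 1e-24, m3 / safe ** 1.5, 0.0)
            kurt = np.where(m2 > 1e-24, m4 / safe ** 2, 0.0)
            if "S" in local_features:
                maps["S"] = skew
            if "K" in local_features:
                maps["K"] = kurt
        if "D" in local_features:
            maps["D"] = np.nanmedian(vals, axis=1)
        if "R" in local_features:
            maps["R"] = np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1)
        if "A" in local_features:
            maps["A"] = np.nanmean(np.abs(dev), axis=1)
        if "Q" in local_features:
            maps["Q"] = np.sqrt(np.nanmean(vals ** 2, axis=1))

    if "E" in local_features or "U" in local_features:
        region = image[mask]
        lo, hi = float(region.min()), float(region.max())
        bins = _bin_indices(np.nan_to_num(vals, nan=lo), lo, hi, n_bins)
        valid = ~np.isnan(vals)
        rows = np.repeat(np.arange(n), vals.shape[1])[valid.ravel()]
        cols = bins.ravel()[valid.ravel()]
        hist = np.zeros((n, n_bins))
        np.add.at(hist, (rows, cols), 1.0)
        p = hist / counts[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        if "E" in local_features:
            maps["E"] = -(p * logp).sum(axis=1)
        if "U" in local_features:
            maps["U"] = (p ** 2).sum(axis=1)

    return {code: maps[code] for code in local_features}


def compute_local_map(image: np.ndarray, mask: np.ndarray, local_feature: str,
                      window_radius: int = 2,
                      n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """One local parametric map as a full-size 2-D array (NaN off the map)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) > 0
    coords, _, counts = _window_values(image, mask, window_radius)
    vals = compute_local_maps(image, mask, (local_feature,),
                              window_radius, n_bins)[local_feature]
    out = np.full(image.shape, np.nan)
    keep = coords[counts >= 4]
    out[keep[:, 0], keep[:, 1]] = vals
    return out


# ---------------------------------------------------------------------------
# global descriptors
# ---------------------------------------------------------------------------

def summarize_map(values, descriptor: str, n_bins: int = N_BINS_DEFAULT) -> float:
    """One of the 12 global descriptors of a map's value distribution.

    Returns NaN (missing, logged) for fewer than 4 valid values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        logger.warning("summarize_map: <4 valid values for descriptor %r",
                       descriptor)
        return float("nan")
    if descriptor == "m":
        return float(values.mean())
    if descriptor == "sd":
        return float(values.std(ddof=1))
    if descriptor == "md":
        return float(np.median(values))
    if descriptor == "iq":
        q75, q25 = np.percentile(values, [75, 25])
        return float(q75 - q25)
    if descriptor == "mn":
        return float(values.min())
    if descriptor == "mx":
        return float(values.max())
    if descriptor == "r":
        return float(values.max() - values.min())
    if descriptor in ("s", "k"):
        m = values.mean()
        m2 = ((values - m) ** 2).mean()
        if m2 <= 1e-24:
            return 0.0
        if descriptor == "s":
            return float(((values - m) ** 3).mean() / m2 ** 1.5)
        return float(((values - m) ** 4).mean() / m2 ** 2)
    if descriptor in ("e", "u"):
        lo, hi = float(values.min()), float(values.max())
        idx = _bin_indices(values, lo, hi, n_bins)
        p = np.bincount(idx, minlength=n_bins) / values.size
        entropy, uniformity = _entropy_uniformity(p)
        return entropy if descriptor == "e" else uniformity
    if descriptor == "p90":
        return float(np.percentile(values, 90))
    raise ValueError(f"unknown descriptor {descriptor!r}")


def ratio_feature(value_a: float, value_v: float, epsilon: float = 1e-9) -> float:
    """Arterial/venous ratio; missing (NaN) when the denominator vanishes."""
    if not (np.isfinite(value_a) and np.isfinite(value_v)):
        return float("nan")
    if abs(value_v) < epsilon:
        logger.warning("ratio_feature: venous value below epsilon; "
                       "feature set to missing")
        return float("nan")
    return float(value_a / value_v)


# ---------------------------------------------------------------------------
# catalogue assembly
# ---------------------------------------------------------------------------

def _phase_code(phase: str) -> str:
    return "A" if phase == "arterial" else "V"


def _region_features(values_by_code: dict, region: str, phase_code: str,
                     descriptors: tuple, n_bins: int) -> dict:
    out = {}
    for code, map_values in values_by_code.items():
        for d in descriptors:
            name = FeatureName(code, d, region, phase_code).render()
            out[name] = summarize_map(map_values, d, n_bins)
    return out


def generate_catalogue(images: dict, tumour_masks: dict, zot_masks: dict,
                       config: FeatureConfig | None = None,
                       subject_id: str = "", label: int | None = None
                       ) -> FeatureVector:
    """Compute the full named catalogue for one nodule.

    Parameters
    ----------
    images, tumour_masks, zot_masks
        Dicts keyed by phase (``arterial``/``venous``) holding
        :class:`PhaseImage` (or arrays), tumour masks and ZOT masks.
        Tumour features use the grey-level image over every mask slice;
        ZOT features use the gradient-magnitude image on the (single) ZOT
        slice.

    Returns a :class:`FeatureVector` with exactly
    ``2*(7+10+1)*12 + 216 + 6 = 654`` entries under the default config.
    """
    cfg = config or FeatureConfig()
    per_phase: dict[str, dict] = {}
    sizes: dict[str, dict] = {}

    for phase in ("arterial", "venous"):
        pc = _phase_code(phase)
        img = images[phase]
        arr = img.voxels if isinstance(img, PhaseImage) else np.asarray(img, float)
        tmask = tumour_masks[phase]
        tmask = (tmask.support if isinstance(tmask, RoiMask) else np.asarray(tmask)) > 0
        zmask = zot_masks[phase]
        zmask = (zmask.support if isinstance(zmask, RoiMask) else np.asarray(zmask)) > 0

        feats = {}
        # tumour: grey-level local maps over all slices
        if arr.ndim == 3:
            pooled = {code: [] for code in cfg.tumour_locals}
            for sl in range(arr.shape[2]):
                if tmask[:, :, sl].sum() == 0:
                    continue
                maps = compute_local_maps(arr[:, :, sl], tmask[:, :, sl],
                                          cfg.tumour_locals,
                                          cfg.window_radius, cfg.n_bins)
                for code, v in maps.items():
                    pooled[code].append(v)
            tmaps = {c: np.concatenate(v) if v else np.empty(0)
                     for c, v in pooled.items()}
            slice2d = arr[:, :, 0]
        else:
            tmaps = compute_local_maps(arr, tmask, cfg.tumour_locals,
                                       cfg.window_radius, cfg.n_bins)
            slice2d = arr
        feats.update(_region_features(tmaps, "T", pc, cfg.descriptors, cfg.n_bins))

        # ZOT: gradient-magnitude local maps + direct global descriptors
        zslice = zmask if zmask.ndim == 2 else zmask[:, :, 0]
        grad = compute_gradient_field(slice2d, cfg.smoothing_sigma).magnitude
        zmaps = compute_local_maps(grad, zslice, cfg.zot_locals,
                                   cfg.window_radius, cfg.n_bins)
        feats.update(_region_features(zmaps, "ZOT", pc, cfg.descriptors, cfg.n_bins))
        gvals = grad[zslice]
        for d in cfg.descriptors:
            name = FeatureName("GLOBAL", d, "ZOT", pc).render()
            feats[name] = summarize_map(gvals, d, cfg.n_bins)

        per_phase[pc] = feats
        sizes[pc] = {"T": float(tmask.sum()), "ZOT": float(zslice.sum())}

    # assemble in stable order: per-phase blocks, then ratios, then sizes
    values: dict[str, float] = {}
    for pc in ("A", "V"):
        values.update(per_phase[pc])
    for name_a, val_a in per_phase["A"].items():
        base = name_a[: name_a.index("[")]
        region = name_a[name_a.index("[") + 1:-1].split(",")[0]
        name_v = f"{base}[{region},V]"
        ratio_name = f"{base}[{region},A/V]"
        values[ratio_name] = ratio_feature(val_a, per_phase["V"][name_v],
                                           cfg.ratio_epsilon)
    for pc in ("A", "V"):
        values[FeatureName("SIZE", "", "T", pc).render()] = sizes[pc]["T"]
        values[FeatureName("SIZE", "", "ZOT", pc).render()] = sizes[pc]["ZOT"]
    values[FeatureName("SIZE", "", "T", "A/V").render()] = ratio_feature(
        sizes["A"]["T"], sizes["V"]["T"], cfg.ratio_epsilon)
    values[FeatureName("SIZE", "", "ZOT", "A/V").render()] = ratio_feature(
        sizes["A"]["ZOT"], sizes["V"]["ZOT"], cfg.ratio_epsilon)

    n_missing = int(sum(1 for v in values.values() if not np.isfinite(v)))
    if n_missing:
        logger.info("catalogue for %s: %d missing features", subject_id, n_missing)
    return FeatureVector(values, subject_id=subject_id, label=label,
                         n_missing=n_missing)
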