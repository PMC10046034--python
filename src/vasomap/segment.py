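"""Cerebrovascular segmentation of bright-vessel angiographic volumes.

The chain mirrors the classic adaptive region-growing recipe:

1. :func:`fit_intensity_model` — a two-component 1-D Gaussian mixture
   (vessels bright, other tissue darker) fitted by EM on masked voxels.
2. :func:`initial_segmentation` — voxel-wise Bayes decision between the two
   components; misses faint, thin vessels.
3. :func:`adaptive_refine` — every 2-D connected component of each axial
   slice gets a search window of adaptive size; within the window a local
   threshold T = (mu_b + mu_o) / 2 is recomputed from in-mask and
   out-of-mask voxels, and super-threshold window voxels are added.
4. :func:`generate_seeds` — all refined voxels plus out-of-mask window
   voxels above their local threshold become seeds for growth.
5. :func:`region_grow_3d` — 26-connected growth from the seeds accepting
   voxels above the global T = (mu_b + mu_o) / 2, with a minimum component
   size filter.

No randomness anywhere; EM initialization is percentile-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class IntensityModel:
    """Two-population intensity statistics: vessels (b) vs other tissue (o)."""

    mu_b: float
    mu_o: float
    sigma_b: float
    sigma_o: float
    weight_b: float
    log_likelihood: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mu_b <= self.mu_o:
            raise ValueError("vessel mean mu_b must exceed tissue mean mu_o")
        if self.sigma_b <= 0 or self.sigma_o <= 0:
            raise ValueError("SDs must be positive")
        if not (0.0 < self.weight_b < 1.0):
            raise ValueError("weight_b must be in (0, 1)")

    @property
    def threshold(self) -> float:
        """Global separation threshold T = (mu_b + mu_o) / 2."""
        return 0.5 * (self.mu_b + self.mu_o)


@dataclass
class SegmentationResult:
    initial_mask: np.ndarray
    refined_mask: np.ndarray
    final_mask: np.ndarray
    seeds: np.ndarray  # (n, 3) voxel coordinates
    local_thresholds: List[dict] = field(default_factory=list)
    model: Optional[IntensityModel] = None
    metrics: Optional[dict] = None


def _log_norm_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def fit_intensity_model(
    volume: np.ndarray,
    brain_mask: Optional[np.ndarray] = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    max_samples: int = 100_000,
) -> IntensityModel:
    """Fit a two-component Gaussian mixture to masked intensities by EM.

    Components are initialized at the 10th/90th intensity percentiles; the
    returned model always reports the brighter component as the vessel
    class.  The per-iteration mean log-likelihood history is recorded (it is
    non-decreasing, the standard EM guarantee).  Raises on (near-)constant
    input, where no two-population model exists.
    """
    vol = np.asarray(volume, dtype=float)
    x = vol[brain_mask] if brain_mask is not None else vol.ravel()
    if x.size == 0:
        raise ValueError("brain mask is empty")
    if x.size > max_samples:  # deterministic thinning
        x = x[:: x.size // max_samples + 1]
    if np.ptp(x) < 1e-9:
        raise ValueError("single-intensity input: cannot fit a two-class model")

    lo, hi = np.percentile(x, [10, 90])
    if hi - lo < 1e-9:
        # heavily imbalanced mixture: split at mid-range instead
        mid = 0.5 * (x.min() + x.max())
        lo = x[x <= mid].mean()
        hi = x[x > mid].mean()
    mu = np.array([lo, hi])
    sd = np.array([x.std(), x.std()]) / 2.0
    sd = np.maximum(sd, 1e-3)
    w = np.array([0.5, 0.5])
    history = []
    for _ in range(max_iter):
        logp = np.stack(
            [np.log(w[k]) + _log_norm_pdf(x, mu[k], sd[k]) for k in range(2)]
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.mean())
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum((resp @ (x**2)) / nk - mu**2, 1e-6))
        w = nk / x.size
        if history and ll - history[-1] < tol:
            history.append(ll)
            break
        history.append(ll)

    bright = int(np.argmax(mu))
    dark = 1 - bright
    if mu[bright] - mu[dark] < 1e-6:
        raise ValueError("EM collapsed to a single component")
    return IntensityModel(
        mu_b=float(mu[bright]),
        mu_o=float(mu[dark]),
        sigma_b=float(sd[bright]),
        sigma_o=float(sd[dark]),
        weight_b=float(w[bright]),
        log_likelihood=tuple(history),
    )


def initial_segmentation(volume: np.ndarray, model: IntensityModel) -> np.ndarray:
    """Bayes classification of every voxel: vessel iff the vessel-class
    posterior is at least the tissue-class posterior."""
    vol = np.asarray(volume, dtype=float)
    log_b = np.log(model.weight_b) + _log_norm_pdf(vol, model.mu_b, model.sigma_b)
    log_o = np.log(1 - model.weight_b) + _log_norm_pdf(vol, model.mu_o, model.sigma_o)
    return log_b >= log_o


def adaptive_refine(
    volume: np.ndarray,
    initial_mask: np.ndarray,
    window_growth: float = 1.0,
) -> Tuple[np.ndarray, List[dict]]:
    """Slice-wise adaptive thresholding around 2-D connected components.

    For each 8-connected component of every axial slice, a search window
    (component bounding box dilated by ``window_growth`` × the component's
    equivalent diameter) defines local class means: mu_b from in-mask window
    voxels, mu_o from out-of-mask window voxels.  Window voxels brighter
    than T = (mu_b + mu_o) / 2 join the mask.  The refined mask is a
    superset of the initial one.  Components whose window contains no
    out-of-mask voxel are skipped and logged.
    """
    if window_growth <= 0:
        raise ValueError("window_growth must be positive")
    vol = np.asarray(volume, dtype=float)
    refined = np.asarray(initial_mask, dtype=bool).copy()
    records: List[dict] = []
    for z in range(vol.shape[0]):
        sl_mask = np.asarray(initial_mask[z], dtype=bool)
        if not sl_mask.any():
            continue
        labels, n = ndimage.label(sl_mask, structure=_STRUCT_8)
        slices = ndimage.find_objects(labels)
        for comp_id, box in enumerate(slices, start=1):
            if box is None:
                continue
            area = int((labels[box] == comp_id).sum())
            diam = 2.0 * np.sqrt(area / np.pi)
            pad = max(int(np.ceil(window_growth * diam)), 1)
            y0 = max(box[0].start - pad, 0)
            y1 = min(box[0].stop + pad, vol.shape[1])
            x0 = max(box[1].start - pad, 0)
            x1 = min(box[1].stop + pad, vol.shape[2])
            win = vol[z, y0:y1, x0:x1]
            win_mask = sl_mask[y0:y1, x0:x1]
            out = ~win_mask
            if not out.any():
                records.append(
                    {"slice": z, "component": comp_id, "skipped": True}
                )
                continue
            mu_b = float(win[win_mask].mean())
            mu_o = float(win[out].mean())
            t = 0.5 * (mu_b + mu_o)
            add = win > t
            refined[z, y0:y1, x0:x1] |= add
            records.append(
                {
                    "slice": z,
                    "component": comp_id,
                    "mu_b": mu_b,
                    "mu_o": mu_o,
                    "threshold": t,
                    "window": (y0, y1, x0, x1),
                    "skipped": False,
                }
            )
    return refined, records


def generate_seeds(
    volume: np.ndarray,
    refined_mask: np.ndarray,
    local_thresholds: Optional[List[dict]] = None,
) -> np.ndarray:
    """Seed voxels for 3-D growth: every refined-mask voxel, plus any
    out-of-mask voxel that exceeds the local threshold of a search window
    covering it (candidate small-vessel detections)."""
    vol = np.asarray(volume, dtype=float)
    mask = np.asarray(refined_mask, dtype=bool)
    seed_mask = mask.copy()
    for rec in local_thresholds or []:
        if rec.get("skipped", False):
            continue
        z = rec["slice"]
        y0, y1, x0, x1 = rec["window"]
        win = vol[z, y0:y1, x0:x1]
        extra = (win > rec["threshold"]) & ~mask[z, y0:y1, x0:x1]
        seed_mask[z, y0:y1, x0:x1] |= extra
    return np.argwhere(seed_mask)


def region_grow_3d(
    volume: np.ndarray,
    seeds: np.ndarray,
    model: IntensityModel,
    min_component_size: int = 5,
) -> np.ndarray:
    """Breadth-first 26-connected growth from the seeds.

    Voxels with intensity strictly above the global T = (mu_b + mu_o) / 2
    are traversable; a component of traversable-or-seed voxels is kept iff
    it contains at least one seed and (after growth) has at least
    ``min_component_size`` voxels.
    """
    seeds = np.asarray(seeds)
    if seeds.size == 0:
        raise ValueError("region growing requires at least one seed")
    vol = np.asarray(volume, dtype=float)
    accept = vol > model.threshold
    seed_mask = np.zeros(vol.shape, dtype=bool)
    seed_mask[tuple(seeds.T)] = True
    # BFS from seeds over `accept` voxels == connected components of
    # (accept | seeds) that contain a seed; the label-based form is
    # equivalent and vectorized (a brute-force queue BFS is the test oracle)
    labels, n = ndimage.label(accept | seed_mask, structure=_STRUCT_26)
    if n == 0:
        return np.zeros(vol.shape, dtype=bool)
    seeded = np.unique(labels[seed_mask])
    seeded = seeded[seeded > 0]
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = seeded[sizes[seeded] >= min_component_size]
    final = np.isin(labels, keep)
    return final


def evaluate_segmentation(pred_mask: np.ndarray, truth_mask: np.ndarray) -> Dict[str, float]:
    """Dice, sensitivity and specificity of a predicted mask, in percent."""
    p = np.asarray(pred_mask, dtype=bool)
    t = np.asarray(truth_mask, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("masks must have the same shape")
    if not t.any():
        raise ValueError("empty truth mask: sensitivity undefined")
    tp = int((p & t).sum())
    fn = int((~p & t).sum())
    fp = int((p & ~t).sum())
    tn = int((~p & ~t).sum())
    dice = 200.0 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return {"dice": dice, "sensitivity": sens, "specificity": spec}


def segment_volume(
    volume: np.ndarray,
    brain_mask: Optional[np.ndarray] = None,
    window_growth: float = 1.0,
    min_component_size: int = 5,
) -> SegmentationResult:
    """Run the full segmentation chain on a (preprocessed) volume."""
    model = fit_intensity_model(volume, brain_mask)
    initial = initial_segmentation(volume, model)
    if brain_mask is not None:
        initial &= np.asarray(brain_mask, dtype=bool)
    refined, thresholds = adaptive_refine(volume, initial, window_growth)
    if brain_mask is not None:
        refined &= np.asarray(brain_mask, dtype=bool)
    seeds = generate_seeds(volume, refined, thresholds)
    if len(seeds) == 0:
        final = np.zeros(volume.shape, dtype=bool)
    else:
        final = region_grow_3d(volume, seeds, model, min_component_size)
        if brain_mask is not None:
            final &= np.asarray(brain_mask, dtype=bool)
    return SegmentationResult(
        initial_mask=initial,
        refined_mask=refined,
        final_mask=final,
        seeds=seeds,
        local_thresholds=thresholds,
        model=model,
    )
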