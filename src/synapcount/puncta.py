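"""Detection, segmentation and measurement of fluorescent synaptic puncta.

The detector follows the classic spot-detection recipe for large-field
confocal mosaics: a multi-resolution, multi-orientation second-order
nonlocal derivative (center-surround second difference) produces per-pixel
features; low-threshold local maxima of the combined response give
high-recall candidates; a supervised classifier trained on labeled
candidates separates true puncta from background noise; accepted puncta are
segmented at 10% of their background-subtracted peak intensity and measured
with six standard morphometric descriptors (mean intensity, size, skewness,
kurtosis, circularity, aspect ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, perimeter_crofton

DEFAULT_SCALES = (1.0, 1.5, 2.5, 4.0)
DEFAULT_N_ORIENTATIONS = 4


@dataclass
class PunctumRecord:
    """One segmented punctum and its six descriptors.

    ``size`` is in um^2 (mask pixel count x pixel area); intensity statistics
    are computed on background-subtracted values inside the mask.  The mask
    is stored compactly as sorted flat pixel indices into an image of shape
    ``image_shape``; ``mask_array()`` rebuilds the boolean mask.
    """

    channel: int
    centroid: tuple[float, float]          # (y, x) pixels, intensity-weighted
    mask: np.ndarray = field(repr=False)   # sorted flat indices
    image_shape: tuple[int, int] = (0, 0)
    mean_intensity: float = 0.0
    size: float = 0.0                      # um^2
    skewness: float = 0.0
    kurtosis: float = 0.0                  # non-excess (normal -> 3)
    circularity: float = 0.0               # 4*pi*A / P^2
    aspect_ratio: float = 1.0              # major/minor axis, >= 1

    @property
    def n_pixels(self) -> int:
        return int(self.mask.size)

    def mask_array(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m.ravel()[self.mask] = True
        return m


@dataclass
class ColocalizationResult:
    n_entities_total: int
    n_entities_both_channels: int
    c: float
    pairing: list[tuple[int, int]]


# --------------------------------------------------------------------------
# Features and candidates
# --------------------------------------------------------------------------

def nld_features(image, scales=DEFAULT_SCALES,
                 n_orientations=DEFAULT_N_ORIENTATIONS):
    """Second-order nonlocal derivative features at several scales/orientations.

    For scale ``s`` and orientation ``theta`` the feature is the second
    difference of the s-smoothed image along theta with step s:
    ``f = S(x) - (S(x + d) + S(x - d)) / 2`` with ``d = s (cos t, sin t)``.
    The response is positive at the center of bright spots of comparable
    radius, ~0 on constant or linearly ramping intensity, and sign-symmetric
    on edges.  Returns an array of shape (n_scales * n_orientations, H, W).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    scales = tuple(scales)
    if not scales or n_orientations < 1:
        raise ValueError("need at least one scale and one orientation")
    if max(scales) * 2 >= min(image.shape):
        raise ValueError("scale too large for this image")
    thetas = np.arange(n_orientations) * np.pi / n_orientations
    maps = []
    for s in scales:
        smooth = ndimage.gaussian_filter(image, sigma=s / 2.0, mode="nearest")
        for t in thetas:
            d = (s * np.sin(t), s * np.cos(t))     # (dy, dx)
            plus = ndimage.shift(smooth, shift=(-d[0], -d[1]), order=1,
                                 mode="nearest")
            minus = ndimage.shift(smooth, shift=(d[0], d[1]), order=1,
                                  mode="nearest")
            maps.append(smooth - 0.5 * (plus + minus))
    return np.stack(maps)


def spot_response(features, scales=DEFAULT_SCALES,
                  n_orientations=DEFAULT_N_ORIENTATIONS):
    """Scalar blob response: max over scales of the min over orientations.

    The orientation minimum suppresses ridges/edges (bright in only some
    orientations); the scale maximum keeps the best-matching resolution.
    """
    per_scale = features.reshape(len(scales), n_orientations,
                                 *features.shape[1:])
    return per_scale.min(axis=1).max(axis=0)


@dataclass
class Candidate:
    channel: int
    peak: tuple[int, int]          # (row, col)
    response: float
    features: np.ndarray


def detect_candidates(image, features=None, low_threshold=1.0,
                      scales=DEFAULT_SCALES,
                      n_orientations=DEFAULT_N_ORIENTATIONS,
                      min_distance=2, channel=1):
    """High-recall candidate puncta: response local maxima above a low bar.

    ``low_threshold`` is on the blob response (intensity units); the default
    only rejects structure far below the noise floor.  Peaks closer than
    ``min_distance`` pixels are merged, keeping the stronger (candidate
    de-duplication).  Each candidate carries its full feature vector plus
    the response and the local raw intensity, for the classifier.
    """
    if low_threshold < 0:
        raise ValueError("low_threshold must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if features is None:
        features = nld_features(image, scales, n_orientations)
    per_scale = features.reshape(len(scales), n_orientations,
                                 *features.shape[1:]).min(axis=1)
    resp = per_scale.max(axis=0)
    # peaks are found per scale (close pairs that merge at a coarse scale
    # stay separate at a finer one), then de-duplicated across scales
    found = {}
    for smap in per_scale:
        # 3x3 local maxima; spacing is enforced by the greedy pass below
        for r, c in peak_local_max(smap, min_distance=1,
                                   threshold_abs=max(low_threshold, 1e-12),
                                   exclude_border=False):
            key = (int(r), int(c))
            found[key] = max(found.get(key, -np.inf), float(resp[r, c]))
    peaks = sorted(found, key=lambda k: -found[k])
    kept: list[tuple[int, int]] = []
    taken = np.zeros(image.shape, dtype=bool)   # suppression footprint
    md = int(np.ceil(min_distance)) - 1
    offs = [(dr, dc) for dr in range(-md, md + 1) for dc in range(-md, md + 1)
            if dr * dr + dc * dc < float(min_distance) ** 2]
    for r, c in peaks:       # greedy de-dup, strongest first
        if taken[r, c]:
            continue
        kept.append((r, c))
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < taken.shape[0] and 0 <= cc < taken.shape[1]:
                taken[rr, cc] = True
    bg = float(np.median(image))
    out = []
    for r, c in sorted(kept):
        fv = np.concatenate([features[:, r, c],
                             [resp[r, c], image[r, c] - bg]])
        out.append(Candidate(channel=channel, peak=(r, c),
                             response=float(resp[r, c]), features=fv))
    return out


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def train_classifier(candidates, labels, seed=0):
    """Fit a seeded random forest on candidate feature vectors.

    ``labels`` are truthy for real puncta, falsy for background.  Raises if
    only one class is present.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.asarray([bool(l) for l in labels])
    if len(y) != len(candidates):
        raise ValueError("labels must match candidates")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = np.stack([c.features for c in candidates])
    clf = RandomForestClassifier(n_estimators=100, random_state=seed,
                                 n_jobs=1)
    clf.fit(X, y)
    return clf


def classify_candidates(candidates, classifier):
    """Return the subset of candidates the classifier accepts as puncta."""
    if not candidates:
        return []
    X = np.stack([c.features for c in candidates])
    keep = classifier.predict(X).astype(bool)
    return [c for c, k in zip(candidates, keep) if k]


# --------------------------------------------------------------------------
# Segmentation and measurement
# --------------------------------------------------------------------------

def segment_punctum(image, peak, background=None, window_radius=24,
                    threshold_fraction=0.10, return_indices=False):
    """Segment one punctum at 10% of its background-subtracted peak.

    ``background`` defaults to the field median.  The mask is the connected
    component (8-connectivity), containing the peak, of pixels whose
    background-subtracted intensity is >= ``threshold_fraction`` times the
    peak's.  Scale-invariant by construction.  Returns a boolean full-field
    mask (or, with ``return_indices``, the compact ``(flat_indices, shape)``
    form); an empty mask signals a peak at or below background.
    """
    image = np.asarray(image, dtype=np.float64)
    r, c = int(peak[0]), int(peak[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError("peak outside image")
    if background is None:
        background = float(np.median(image))
    sub = np.clip(image - background, 0.0, None)
    # refine the peak to the local maximum of the 3x3 neighborhood
    r0, r1 = max(r - 1, 0), min(r + 2, image.shape[0])
    c0, c1 = max(c - 1, 0), min(c + 2, image.shape[1])
    loc = np.unravel_index(np.argmax(sub[r0:r1, c0:c1]), (r1 - r0, c1 - c0))
    r, c = r0 + int(loc[0]), c0 + int(loc[1])
    peak_val = sub[r, c]
    if peak_val <= 0:
        if return_indices:
            return np.empty(0, dtype=np.int64), image.shape
        return np.zeros(image.shape, dtype=bool)
    wr0, wr1 = max(r - window_radius, 0), min(r + window_radius + 1,
                                              image.shape[0])
    wc0, wc1 = max(c - window_radius, 0), min(c + window_radius + 1,
                                              image.shape[1])
    win = sub[wr0:wr1, wc0:wc1] >= threshold_fraction * peak_val
    lab = cc_label(win, connectivity=2)
    comp = lab[r - wr0, c - wc0]
    sel = lab == comp
    wys, wxs = np.nonzero(sel)
    flat = (wys + wr0) * image.shape[1] + (wxs + wc0)
    flat.sort()
    if return_indices:
        return flat, image.shape
    mask = np.zeros(image.shape, dtype=bool)
    mask.ravel()[flat] = True
    return mask


def measure_punctum(image, mask, pixel_size=84.0, channel=1,
                    background=None):
    """Compute the six punctum descriptors on a segmented mask.

    mean intensity: mean background-subtracted intensity over the mask;
    size: |mask| x pixel area (um^2); skewness/kurtosis: standardized 3rd
    and 4th moments of within-mask intensities (kurtosis non-excess);
    circularity: 4*pi*A/P^2 with the Crofton perimeter of the mask;
    aspect ratio: major/minor axis of the intensity-weighted second-moment
    ellipse.
    """
    image = np.asarray(image, dtype=np.float64)
    if isinstance(mask, tuple):           # compact form: (flat indices, shape)
        flat, shape = np.asarray(mask[0]), tuple(mask[1])
    else:
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise ValueError("measure_punctum expects a boolean mask")
        flat, shape = np.flatnonzero(mask.ravel()), mask.shape
    if flat.size == 0:
        raise ValueError("empty mask")
    if background is None:
        background = float(np.median(image))
    vals = np.clip(image.ravel()[flat] - background, 0.0, None)
    ys, xs = np.divmod(flat, shape[1])
    w = vals.sum()
    if w <= 0:
        w = float(len(vals))
        weights = np.ones_like(vals)
    else:
        weights = vals
    cy = float((weights * ys).sum() / weights.sum())
    cx = float((weights * xs).sum() / weights.sum())
    dy, dx = ys - cy, xs - cx
    myy = float((weights * dy * dy).sum() / weights.sum())
    mxx = float((weights * dx * dx).sum() / weights.sum())
    mxy = float((weights * dx * dy).sum() / weights.sum())
    tr, det = mxx + myy, mxx * myy - mxy * mxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + np.sqrt(disc)
    l2 = max(tr / 2.0 - np.sqrt(disc), 1e-12)
    # degenerate (single-pixel) masks have no orientation: aspect 1
    aspect = float(np.sqrt(l1 / l2)) if l1 > 1e-12 else 1.0

    # small crop for the perimeter computation
    y0, x0 = ys.min(), xs.min()
    crop = np.zeros((ys.max() - y0 + 1, xs.max() - x0 + 1), dtype=bool)
    crop[ys - y0, xs - x0] = True
    area_px = int(flat.size)
    # the Crofton estimate underestimates tiny perimeters; the isoperimetric
    # minimum 2*sqrt(pi*A) bounds it below so circularity stays <= 1
    perim = max(perimeter_crofton(crop, directions=4),
                2.0 * np.sqrt(np.pi * area_px))
    circ = 4.0 * np.pi * area_px / (perim * perim)

    n = len(vals)
    sd = vals.std()
    if n > 2 and sd > 0:
        z = (vals - vals.mean()) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4)) if n > 3 else 3.0
    else:
        skew, kurt = 0.0, 3.0
    return PunctumRecord(
        channel=channel, centroid=(cy, cx), mask=flat,
        image_shape=shape,
        mean_intensity=float(vals.mean()),
        size=area_px * pixel_size * pixel_size / 1e6,
        skewness=skew, kurtosis=kurt,
        circularity=float(circ), aspect_ratio=aspect)


# --------------------------------------------------------------------------
# Densities and colocalization
# --------------------------------------------------------------------------

def puncta_density(records, field_area_um2: float) -> float:
    """Puncta per 100 um^2."""
    if field_area_um2 <= 0:
        raise ValueError("field area must be positive")
    return 100.0 * len(records) / field_area_um2


def colocalization(records_ch1, records_ch2, method="overlap",
                   min_overlap_frac=0.25, max_dist_nm=200.0,
                   pixel_size=84.0) -> ColocalizationResult:
    """Object-based colocalization with one-to-one pairing.

    ``method='overlap'`` (default): two puncta are the same entity iff their
    masks overlap by at least ``min_overlap_frac`` of the smaller mask
    (0 reduces to "share >= 1 pixel"); candidate pairs are matched greedily
    by decreasing overlap, ties broken by centroid distance.
    ``method='distance'``: entities are centroid pairs closer than
    ``max_dist_nm``, matched greedily by increasing distance.

    c = paired / total entities, a paired punctum counting once.
    """
    from scipy.spatial import cKDTree

    n1, n2 = len(records_ch1), len(records_ch2)
    if n1 == 0 or n2 == 0:
        return ColocalizationResult(n_entities_total=n1 + n2,
                                    n_entities_both_channels=0,
                                    c=0.0, pairing=[])
    c1 = np.array([r.centroid for r in records_ch1])
    c2 = np.array([r.centroid for r in records_ch2])
    tree2 = cKDTree(c2)
    pairs_scored = []
    if method == "overlap":
        # masks can only overlap if centroids are close; 30 px is generous
        # for puncta a few pixels across
        neighbor_lists = cKDTree(c1).query_ball_tree(tree2, 30.0)
        for i, js in enumerate(neighbor_lists):
            a = records_ch1[i]
            for j in js:
                b = records_ch2[j]
                ov = np.intersect1d(a.mask, b.mask,
                                    assume_unique=True).size
                if ov == 0:
                    continue
                smaller = min(a.n_pixels, b.n_pixels)
                if ov < max(1, int(np.ceil(min_overlap_frac * smaller))):
                    continue
                dist = float(np.hypot(*(c1[i] - c2[j])))
                pairs_scored.append((-ov, dist, i, j))
    elif method == "distance":
        max_px = max_dist_nm / pixel_size
        neighbor_lists = cKDTree(c1).query_ball_tree(tree2, max_px)
        for i, js in enumerate(neighbor_lists):
            for j in js:
                dist = float(np.hypot(*(c1[i] - c2[j])))
                pairs_scored.append((dist, 0.0, i, j))
    else:
        raise ValueError(f"unknown method {method!r}")

    pairs_scored.sort()
    used1, used2, pairing = set(), set(), []
    for _, _, i, j in pairs_scored:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairing.append((i, j))
    n_both = len(pairing)
    n_total = n1 + n2 - n_both
    c = n_both / n_total if n_total else 0.0
    return ColocalizationResult(n_entities_total=n_total,
                                n_entities_both_channels=n_both,
                                c=c, pairing=pairing)


# --------------------------------------------------------------------------
# Field-level driver
# --------------------------------------------------------------------------

def detect_puncta(image, classifier, pixel_size=84.0, low_threshold=1.0,
                  scales=DEFAULT_SCALES,
                  n_orientations=DEFAULT_N_ORIENTATIONS, channel=1):
    """Candidates -> classifier -> segmentation -> measured records."""
    image = np.asarray(image, dtype=np.float64)
    cands = detect_candidates(image, low_threshold=low_threshold,
                              scales=scales, n_orientations=n_orientations,
                              channel=channel)
    accepted = classify_candidates(cands, classifier)
    bg = float(np.median(image))
    segmented = []
    for cand in accepted:
        flat, shape = segment_punctum(image, cand.peak, background=bg,
                                      return_indices=True)
        if flat.size:
            segmented.append((cand.peak, flat, shape))
    segmented = _split_merged_masks(segmented)
    return [measure_punctum(image, (flat, shape), pixel_size=pixel_size,
                            channel=channel, background=bg)
            for _, flat, shape in segmented]


def _split_merged_masks(segmented):
    """Resolve masks that swallowed a neighbor: nearest-peak assignment.

    Each pixel of a mask is kept only if its nearest accepted peak is the
    mask's own; the surviving pixels are re-restricted to the connected
    component containing the peak.
    """
    from scipy.spatial import cKDTree

    if len(segmented) < 2:
        return segmented
    peaks = np.array([p for p, _, _ in segmented], dtype=float)
    tree = cKDTree(peaks)
    out = []
    for i, (peak, flat, shape) in enumerate(segmented):
        ys, xs = np.divmod(flat, shape[1])
        _, owner = tree.query(np.column_stack([ys, xs]).astype(float))
        if np.all(owner == i):
            out.append((peak, flat, shape))
            continue
        keep = owner == i
        if not keep.any():
            continue
        yk, xk = ys[keep], xs[keep]
        y0, x0 = yk.min(), xk.min()
        crop = np.zeros((yk.max() - y0 + 1, xk.max() - x0 + 1), dtype=bool)
        crop[yk - y0, xk - x0] = True
        lab = cc_label(crop, connectivity=2)
        comp = lab[peak[0] - y0, peak[1] - x0] \
            if (0 <= peak[0] - y0 < crop.shape[0]
                and 0 <= peak[1] - x0 < crop.shape[1]) else 0
        if comp == 0:
            continue
        cys, cxs = np.nonzero(lab == comp)
        new_flat = (cys + y0) * shape[1] + (cxs + x0)
        new_flat.sort()
        out.append((peak, new_flat, shape))
    return out


def analyze_field(image2ch, classifier, field_area_um2, pixel_size=84.0,
                  coloc_method="overlap", **detect_kw):
    """Measure both channels of a field: records, densities and c.

    Returns ``(records_ch1, records_ch2, summary_dict)`` where the summary
    holds dPSD95-like, dSAP102-like densities (puncta/100 um^2) and the
    colocalization index.
    """
    rec1 = detect_puncta(image2ch[0], classifier, pixel_size=pixel_size,
                         channel=1, **detect_kw)
    rec2 = detect_puncta(image2ch[1], classifier, pixel_size=pixel_size,
                         channel=2, **detect_kw)
    coloc = colocalization(rec1, rec2, method=coloc_method,
                           pixel_size=pixel_size)
    summary = {
        "d_ch1": puncta_density(rec1, field_area_um2),
        "d_ch2": puncta_density(rec2, field_area_um2),
        "c": coloc.c,
        "n_ch1": len(rec1),
        "n_ch2": len(rec2),
        "n_both": coloc.n_entities_both_channels,
    }
    return rec1, rec2, summary


def records_to_frame(records, pixel_size=84.0):
    """Flatten PunctumRecords to a DataFrame (documented column order)."""
    import pandas as pd

    rows = [(r.channel, r.centroid[1], r.centroid[0], r.mean_intensity,
             r.size, r.skewness, r.kurtosis, r.circularity, r.aspect_ratio)
            for r in records]
    return pd.DataFrame(rows, columns=[
        "channel", "x_px", "y_px", "mean_intensity", "size_um2",
        "skewness", "kurtosis", "circularity", "aspect_ratio"])
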