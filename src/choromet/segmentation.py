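"""Three-boundary layer segmentation of enhanced OCT B-scans.

Each B-scan is reduced to three per-A-scan boundary depths:

* **ILM** (internal limiting membrane) — the first strong dark-to-bright
  transition (vitreous to retina);
* **mid-RPE** — the intensity peak of the retinal pigment epithelium band,
  the brightest reflector below the ILM, taken as the retina/choroid divider;
* **CSI** (choroid-scleral interface) — the bright-to-dark transition at the
  posterior choroid boundary.

Boundaries are found sequentially as minimum-cost paths across A-scans by
dynamic programming on directional axial-gradient (or intensity) cost images,
with a per-step vertical smoothness penalty and a hard maximum step.  Each
boundary is searched in the band below the previous one, which enforces the
ILM <= mid-RPE <= CSI ordering by construction.  Integer paths are refined to
sub-pixel precision by parabolic interpolation of the data cost.

The module also provides the layer-mask derivation and the Dice overlap
coefficient used to score segmentations against reference masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import OCTVolume

__all__ = [
    "SurfaceSet",
    "SegmentationParams",
    "segment_bscan",
    "segment_volume",
    "layer_masks",
    "dice",
]


@dataclass
class SurfaceSet:
    """Per-(B-scan, A-scan) depths of the three boundaries, in fractional pixels.

    ``valid`` marks A-scans where all three boundaries were found; the
    ordering invariant ``ilm <= midrpe <= csi`` holds wherever valid.
    """

    ilm_px: np.ndarray
    midrpe_px: np.ndarray
    csi_px: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ilm_px = np.asarray(self.ilm_px, dtype=np.float64)
        self.midrpe_px = np.asarray(self.midrpe_px, dtype=np.float64)
        self.csi_px = np.asarray(self.csi_px, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {self.ilm_px.shape, self.midrpe_px.shape, self.csi_px.shape, self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("all surface arrays must share one (n_bscans, n_ascans) shape")
        v = self.valid
        if np.any(self.ilm_px[v] > self.midrpe_px[v] + 1e-9) or np.any(
            self.midrpe_px[v] > self.csi_px[v] + 1e-9
        ):
            raise ValueError("ordering invariant violated: require ilm <= midrpe <= csi")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ilm_px.shape

    def retina_thickness_px(self) -> np.ndarray:
        return self.midrpe_px - self.ilm_px

    def choroid_thickness_px(self) -> np.ndarray:
        return self.csi_px - self.midrpe_px


@dataclass
class SegmentationParams:
    """Boundary-search parameters.

    ``smoothness`` is the DP cost per pixel of vertical step between adjacent
    A-scans; ``max_step_px`` the hard step bound.  The anatomical band bounds
    (um) restrict each boundary's search region relative to the previous one:
    the mid-RPE lies between ``min_retina_um`` and ``max_retina_um`` below the
    ILM, the CSI between ``min_choroid_um`` and ``max_choroid_um`` below the
    mid-RPE.  They keep the search away from the compensated image's deep
    noise-amplification tail, which adaptive compensation inflates near the
    bottom of the scan.  ``gradient_floor`` flags featureless A-scans (max
    |axial gradient| below it) as invalid.
    """

    smoothness: float = 0.02
    max_step_px: int = 5
    min_retina_um: float = 120.0
    max_retina_um: float = 500.0
    min_choroid_um: float = 80.0
    max_choroid_um: float = 700.0
    bottom_margin_frac: float = 0.08
    gradient_floor: float = 1e-3
    max_invalid_fraction: float = 0.2


def _dp_path(cost: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Minimum-cost left-to-right path through a (depth, n_ascans) cost image.

    Vertical moves are limited to ``max_step_px`` per column and charged
    ``smoothness`` per pixel of step.  Returns integer depths per column.
    """
    depth, ncols = cost.shape
    ms = params.max_step_px
    acc = cost[:, 0].copy()
    steps = np.empty((ncols, depth), dtype=np.int8)
    big = np.inf
    for a in range(1, ncols):
        best = np.full(depth, big)
        arg = np.zeros(depth, dtype=np.int8)
        for s in range(-ms, ms + 1):
            # candidate: previous column's depth (z - s) feeding depth z
            cand = np.full(depth, big)
            if s >= 0:
                cand[s:] = acc[: depth - s] if s else acc
            else:
                cand[:s] = acc[-s:]
            cand = cand + params.smoothness * abs(s)
            better = cand < best
            best[better] = cand[better]
            arg[better] = s
        acc = best + cost[:, a]
        steps[a] = arg
    path = np.empty(ncols, dtype=np.int64)
    path[-1] = int(np.argmin(acc))
    for a in range(ncols - 1, 0, -1):
        path[a - 1] = path[a] - steps[a, path[a]]
    return path


def _subpixel(cost: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Parabolic sub-pixel refinement of an integer path on its data cost."""
    depth = cost.shape[0]
    z = path.astype(np.float64)
    cols = np.arange(path.size)
    interior = (path > 0) & (path < depth - 1)
    zi = path[interior]
    ci = cols[interior]
    c0 = cost[zi - 1, ci]
    c1 = cost[zi, ci]
    c2 = cost[zi + 1, ci]
    denom = c0 - 2.0 * c1 + c2
    ok = np.isfinite(c0) & np.isfinite(c2) & (denom > 1e-12)
    delta = np.zeros_like(c1)
    delta[ok] = 0.5 * (c0[ok] - c2[ok]) / denom[ok]
    z[interior] += np.clip(delta, -0.5, 0.5)
    return z


def _band_cost(base: np.ndarray, lower: np.ndarray, upper: np.ndarray | None = None) -> np.ndarray:
    """Cost image normalized to [0, 1] with everything outside [lower, upper) disabled.

    Normalization puts the DP smoothness penalty on a scale comparable across
    boundaries and enhancement settings.
    """
    depth = base.shape[0]
    zidx = np.arange(depth)[:, None]
    cost = base.astype(np.float64).copy()
    cost[zidx < lower[None, :]] = np.inf
    if upper is not None:
        cost[zidx >= upper[None, :]] = np.inf
    finite = np.isfinite(cost)
    if np.any(finite):
        lo = cost[finite].min()
        hi = cost[finite].max()
        cost[finite] = (cost[finite] - lo) / (hi - lo + 1e-12)
    return cost


def segment_bscan(
    image: np.ndarray, axial_um_per_px: float, params: SegmentationParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Segment one enhanced B-scan into (ilm, midrpe, csi, valid) per A-scan.

    Boundaries come out in fractional pixels; A-scans whose gradient energy
    falls below ``gradient_floor`` are flagged invalid (their depths are
    placeholders and must be masked by the caller).  ``axial_um_per_px``
    converts the anatomical band bounds to pixels.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D B-scan")
    depth, ncols = img.shape
    grad = np.gradient(img, axis=0)
    valid = np.max(np.abs(grad), axis=0) >= params.gradient_floor
    if not np.any(valid):
        zeros = np.zeros(ncols)
        return zeros, zeros.copy(), zeros.copy(), valid

    px = lambda um: max(1, int(round(um / axial_um_per_px)))
    bottom = depth - max(2, int(round(params.bottom_margin_frac * depth)))

    # mid-RPE first: the RPE band is the brightest, most reliable reflector,
    # so its intensity-peak path anchors the other two searches
    rpe_cost = _band_cost(-img, np.ones(ncols), np.full(ncols, bottom))
    rpe_i = _dp_path(rpe_cost, params)
    midrpe = _subpixel(rpe_cost, rpe_i)

    # ILM: strongest dark-to-bright axial gradient above the retinal band
    ilm_cost = _band_cost(-grad, np.ones(ncols), rpe_i - px(params.min_retina_um))
    ilm_i = _dp_path(ilm_cost, params)
    ilm = _subpixel(ilm_cost, ilm_i)

    # CSI: strongest bright-to-dark transition within the choroidal band
    csi_cost = _band_cost(
        grad,
        rpe_i + px(params.min_choroid_um),
        np.minimum(rpe_i + px(params.max_choroid_um), bottom),
    )
    csi_i = _dp_path(csi_cost, params)
    csi = _subpixel(csi_cost, csi_i)

    # enforce ordering after sub-pixel refinement
    midrpe = np.maximum(midrpe, ilm)
    csi = np.maximum(csi, midrpe)
    return ilm, midrpe, csi, valid


def segment_volume(vol: OCTVolume, params: SegmentationParams | None = None) -> SurfaceSet:
    """Segment every B-scan and smooth each surface across B-scans (median, window 3).

    B-scans whose invalid fraction exceeds ``max_invalid_fraction`` are
    treated as corrupted: their surfaces are linearly interpolated from the
    neighboring B-scans and the event is recorded in ``meta['interpolated_bscans']``.
    The volume-level flag ``meta['poor_quality']`` is set when more than
    ``max_invalid_fraction`` of all A-scans are invalid.
    """
    params = params or SegmentationParams()
    nb, _, na = vol.shape
    ilm = np.zeros((nb, na))
    rpe = np.zeros((nb, na))
    csi = np.zeros((nb, na))
    valid = np.zeros((nb, na), dtype=bool)
    axial_um = vol.axial_mm_per_px * 1000.0
    for b in range(nb):
        ilm[b], rpe[b], csi[b], valid[b] = segment_bscan(vol.intensities[b], axial_um, params)

    bad_bscans = [
        int(b) for b in range(nb) if np.mean(~valid[b]) > params.max_invalid_fraction
    ]
    good = np.setdiff1d(np.arange(nb), bad_bscans)
    if bad_bscans and good.size >= 2:
        for surf in (ilm, rpe, csi):
            for a in range(na):
                surf[bad_bscans, a] = np.interp(bad_bscans, good, surf[good, a])
        valid[bad_bscans] = True
    elif bad_bscans:
        valid[bad_bscans] = False

    # across-B-scan median smoothing, window 3
    if nb >= 3:
        for surf in (ilm, rpe, csi):
            surf[:] = ndimage.median_filter(surf, size=(3, 1), mode="nearest")
    rpe = np.maximum(rpe, ilm)
    csi = np.maximum(csi, rpe)

    meta = {
        "interpolated_bscans": bad_bscans,
        "invalid_fraction": float(np.mean(~valid)),
        "poor_quality": bool(np.mean(~valid) > params.max_invalid_fraction),
    }
    return SurfaceSet(ilm, rpe, csi, valid, meta=meta)


def layer_masks(surfaces: SurfaceSet, depth_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Voxel masks of the retina (ILM..mid-RPE) and choroid (mid-RPE..CSI).

    A voxel at integer depth ``z`` belongs to a layer when
    ``top <= z < bottom`` against the fractional boundary depths, so the two
    masks are disjoint and exactly consistent with the surfaces.  Invalid
    A-scans contribute no voxels.  Shapes are ``(n_bscans, depth_px, n_ascans)``.
    """
    nb, na = surfaces.shape
    z = np.arange(depth_px)[None, :, None]
    v = surfaces.valid[:, None, :]
    ilm = surfaces.ilm_px[:, None, :]
    rpe = surfaces.midrpe_px[:, None, :]
    csi = surfaces.csi_px[:, None, :]
    retina = (z >= ilm) & (z < rpe) & v
    choroid = (z >= rpe) & (z < csi) & v
    return retina, choroid


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|a & b| / (|a| + |b|)``; two empty masks score 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def save_surfaces_tsv(surfaces: SurfaceSet, path) -> None:
    """Write a SurfaceSet as TSV: bscan, ascan, ilm_px, midrpe_px, csi_px, valid."""
    import pandas as pd

    nb, na = surfaces.shape
    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    pd.DataFrame(
        {
            "bscan": bb.ravel(),
            "ascan": aa.ravel(),
            "ilm_px": surfaces.ilm_px.ravel(),
            "midrpe_px": surfaces.midrpe_px.ravel(),
            "csi_px": surfaces.csi_px.ravel(),
            "valid": surfaces.valid.ravel().astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def load_surfaces_tsv(path) -> SurfaceSet:
    """Read a SurfaceSet TSV (accepts externally produced segmentations)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    nb = int(df["bscan"].max()) + 1
    na = int(df["ascan"].max()) + 1

    def grid(col: str) -> np.ndarray:
        out = np.zeros((nb, na))
        out[df["bscan"].to_numpy(), df["ascan"].to_numpy()] = df[col].to_numpy()
        return out

    return SurfaceSet(grid("ilm_px"), grid("midrpe_px"), grid("csi_px"), grid("valid") > 0)
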