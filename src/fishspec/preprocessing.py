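"""Hypercube-to-voxel preprocessing and spectral pretreatments.

Fixed pipeline order: calibrate -> exposure-scale -> mask -> voxelize ->
flag outliers -> (optional pretreatment).  Each step logs the parameters
it applied through the module logger.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import Hypercube, VoxelTable, make_voxel_frame

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# radiometric calibration

def calibrate_cube(
    raw: Hypercube,
    white: np.ndarray | None = None,
    dark: np.ndarray | None = None,
) -> Hypercube:
    """Convert raw counts to reflectance: (raw - dark) / (white - dark).

    ``white``/``dark`` default to the frames stored on the cube.  Every
    element of ``white - dark`` must be positive; the error names the
    first offending band.
    """
    white = raw.white_frame if white is None else white
    dark = raw.dark_frame if dark is None else dark
    if white is None or dark is None:
        raise ValueError("calibration requires white and dark reference frames")
    white = np.broadcast_to(np.asarray(white, dtype=float), raw.data.shape)
    dark = np.broadcast_to(np.asarray(dark, dtype=float), raw.data.shape)
    denom = white - dark
    bad = denom <= 0
    if np.any(bad):
        band = int(np.nonzero(bad.any(axis=(0, 1)))[0][0])
        raise ValueError(
            f"white - dark is non-positive at band index {band} "
            f"({raw.wavelengths[band]:.1f} nm)"
        )
    reflectance = (raw.data - dark) / denom
    log.info("calibrated cube to reflectance (mode=%s)", raw.mode)
    return Hypercube(
        data=reflectance,
        wavelengths=raw.wavelengths,
        mode=raw.mode,
        exposure_ms=raw.exposure_ms,
        saturation_ceiling=None,
    )


def scale_for_exposure(cube: Hypercube, reference_exposure_ms: float) -> Hypercube:
    """Rescale intensities to a common exposure time (linear assumption)."""
    if reference_exposure_ms <= 0 or cube.exposure_ms <= 0:
        raise ValueError("exposure times must be positive")
    factor = reference_exposure_ms / cube.exposure_ms
    log.info("exposure scaling x%.4g (%.4g -> %.4g ms)",
             factor, cube.exposure_ms, reference_exposure_ms)
    ceiling = cube.saturation_ceiling
    return Hypercube(
        data=cube.data * factor,
        wavelengths=cube.wavelengths,
        mode=cube.mode,
        exposure_ms=reference_exposure_ms,
        white_frame=cube.white_frame,
        dark_frame=cube.dark_frame,
        saturation_ceiling=None if ceiling is None else ceiling * factor,
    )


# ---------------------------------------------------------------------------
# masking and voxelization

def build_mask(
    cube: Hypercube,
    strategy: str = "reference-band",
    threshold: float = 0.2,
    reference_band: int | None = None,
) -> np.ndarray:
    """Boolean fillet mask: threshold an intensity image, keep the
    largest connected foreground component.

    ``reference-band`` thresholds a single high-contrast band (middle
    band by default); ``band-threshold`` thresholds the mean over all
    bands.  ``threshold`` is a fraction of the image's intensity range.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if strategy == "reference-band":
        band = reference_band if reference_band is not None else cube.shape[2] // 2
        image = cube.data[:, :, band]
    elif strategy == "band-threshold":
        image = cube.data.mean(axis=2)
    else:
        raise ValueError(f"unknown mask strategy {strategy!r}")
    lo, hi = float(image.min()), float(image.max())
    fg = image > lo + threshold * (hi - lo)
    if not fg.any():
        raise ValueError("empty foreground: no pixel above the mask threshold")
    labels, n = ndimage.label(fg)
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=range(1, n + 1))) + 1
    mask = labels == largest
    log.info("mask: strategy=%s threshold=%.3f area=%d px", strategy, threshold,
             int(mask.sum()))
    return mask


def voxelize(
    cube: Hypercube,
    mask: np.ndarray,
    block: int = 10,
    *,
    min_in_mask: float = 0.5,
    fillet_id="fillet_1",
    species: str = "unknown",
    day=0,
) -> VoxelTable:
    """Spatially average the masked cube over ``block`` x ``block`` tiles.

    One voxel per complete tile with at least ``min_in_mask`` of its
    pixels inside the mask; the voxel spectrum is the mean over the
    tile's in-mask pixels.  Incomplete edge tiles are dropped.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    rows, cols, _ = cube.shape
    if block > rows or block > cols:
        raise ValueError("block larger than image")
    if mask.shape != (rows, cols):
        raise ValueError("mask shape does not match cube")
    spectra, coords = [], []
    for br in range(rows // block):
        for bc in range(cols // block):
            sl = (slice(br * block, (br + 1) * block),
                  slice(bc * block, (bc + 1) * block))
            tile_mask = mask[sl]
            if tile_mask.mean() < min_in_mask:
                continue
            tile = cube.data[sl]
            spectra.append(tile[tile_mask].mean(axis=0))
            coords.append((br, bc))
    log.info("voxelize: block=%d -> %d voxels", block, len(spectra))
    if not spectra:
        frame = make_voxel_frame(
            np.empty((0, cube.shape[2])), cube.wavelengths,
            fillet_id=fillet_id, species=species, day=day,
        )
        return VoxelTable(frame=frame, mode=cube.mode)
    frame = make_voxel_frame(
        np.stack(spectra), cube.wavelengths,
        fillet_id=fillet_id, species=species, day=day, block_coords=coords,
    )
    return VoxelTable(frame=frame, mode=cube.mode)


def flag_outlier_voxels(
    cube: Hypercube,
    table: VoxelTable,
    mask: np.ndarray,
    frac: float = 0.10,
    k_sd: float = 2.0,
    block: int = 10,
) -> VoxelTable:
    """Exclude voxels dominated by outlying pixels (saturation, grooves).

    Per-band mean and SD are computed over all in-mask fillet pixels.  A
    voxel is excluded (``kept=False``) when, at any band, strictly more
    than ``frac`` of its member pixels deviate from the band mean by
    more than ``k_sd`` standard deviations.  Idempotent: re-running on
    the flagged table changes nothing.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    fg = cube.data[mask]  # (n_px, bands)
    band_mean = fg.mean(axis=0)
    band_sd = fg.std(axis=0)
    frame = table.frame.copy()
    kept = frame["kept"].to_numpy(dtype=bool).copy()
    for i, (br, bc) in enumerate(zip(frame["block_row"], frame["block_col"])):
        sl = (slice(br * block, (br + 1) * block),
              slice(bc * block, (bc + 1) * block))
        tile_mask = mask[sl]
        px = cube.data[sl][tile_mask]  # member pixels of this voxel
        with np.errstate(invalid="ignore"):
            outlying = np.abs(px - band_mean) > k_sd * band_sd
        frac_out = outlying.mean(axis=0)  # per band
        if np.any(frac_out > frac):
            kept[i] = False
    n_excl = int((~kept).sum())
    log.info("outlier rule: frac=%.2f k_sd=%.1f -> %d voxels excluded",
             frac, k_sd, n_excl)
    frame["kept"] = kept
    return VoxelTable(frame=frame, mode=table.mode)


# ---------------------------------------------------------------------------
# spectral pretreatments

def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum center and scale to unit
    sample SD (ddof=1).  Errors on a constant spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    sd = spectrum.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return (spectrum - spectrum.mean()) / sd


def pretreat_spectrum(
    spectrum: np.ndarray,
    method: str = "SNV",
    window: int = 11,
    poly_order: int = 2,
) -> np.ndarray:
    """Apply SNV and/or Savitzky-Golay smoothing to one spectrum."""
    if method not in ("SNV", "SavitzkyGolay", "SNV+SavitzkyGolay"):
        raise ValueError(f"unknown pretreatment {method!r}")
    out = np.asarray(spectrum, dtype=float)
    if "SavitzkyGolay" in method:
        if window % 2 == 0:
            raise ValueError("smoothing window must be odd")
        if window <= poly_order:
            raise ValueError("smoothing window must exceed the polynomial order")
        out = savgol_filter(out, window_length=window, polyorder=poly_order)
    if "SNV" in method:
        out = snv(out)
    return out


class SNVTransformer(BaseEstimator, TransformerMixin):
    """Row-wise standard normal variate as an sklearn transformer.

    Stateless (``fit`` only validates); composes with pipelines ahead of
    any classifier or decomposition.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of spectra")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("SNV undefined for a constant spectrum")
        return (X - X.mean(axis=1, keepdims=True)) / sd


def preprocess_cube(
    cube: Hypercube,
    *,
    block: int = 10,
    outlier_frac: float = 0.10,
    sd_mult: float = 2.0,
    mask_threshold: float = 0.2,
    reference_exposure_ms: float | None = None,
    fillet_id="fillet_1",
    species: str = "unknown",
    day=0,
) -> tuple[VoxelTable, np.ndarray]:
    """Full preprocessing chain on one cube; returns (table, mask).

    Order: calibrate (reflectance modes with frames) -> exposure scale
    (if a reference is given) -> mask -> voxelize -> outlier flagging.
    """
    work = cube
    if cube.white_frame is not None and cube.dark_frame is not None:
        work = calibrate_cube(work)
    if reference_exposure_ms is not None:
        work = scale_for_exposure(work, reference_exposure_ms)
    mask = build_mask(work, threshold=mask_threshold)
    table = voxelize(work, mask, block=block,
                     fillet_id=fillet_id, species=species, day=day)
    table = flag_outlier_voxels(work, table, mask, frac=outlier_frac,
                                k_sd=sd_mult, block=block)
    return table, mask
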