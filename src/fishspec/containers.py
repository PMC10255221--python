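"""Core data containers shared across the pipeline.

The analysis unit flow is: line-scan ``Hypercube`` (rows x cols x bands)
-> masked, 10x10 spatially averaged ``VoxelTable`` (one mean spectrum per
block) -> per-mode classifiers -> decision-level fusion.

Three spectral modes are supported:

* ``FL``     fluorescence emission under 365 nm excitation, 60 bands, 438-718 nm
* ``VISNIR`` visible/near-infrared reflectance, 125 bands, 419-1007 nm
* ``SWIR``   short-wave infrared reflectance, 287 bands, 842-2532 nm
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FL = "FL"
VISNIR = "VISNIR"
SWIR = "SWIR"
MODES = (FL, VISNIR, SWIR)

#: bands, wavelength range (nm) per mode
MODE_BANDS: dict[str, tuple[int, float, float]] = {
    FL: (60, 438.0, 718.0),
    VISNIR: (125, 419.0, 1007.0),
    SWIR: (287, 842.0, 2532.0),
}

#: default spatial geometry (rows, cols) of a line-scan cube per mode
MODE_SHAPE: dict[str, tuple[int, int]] = {
    FL: (500, 280),
    VISNIR: (500, 280),
    SWIR: (384, 350),
}

#: fillet regions used for spatial heterogeneity and region-specific models
REGIONS = ("head_top", "head_bottom", "tail_top", "tail_bottom")


def mode_wavelengths(mode: str) -> np.ndarray:
    """Evenly spaced band-center wavelengths (nm) for a spectral mode."""
    try:
        n, lo, hi = MODE_BANDS[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}") from None
    return np.linspace(lo, hi, n)


@dataclass
class Hypercube:
    """A 3-D spectral image: two spatial axes by one spectral axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Raw counts or reflectance.
    wavelengths : ndarray, shape (bands,)
        Strictly increasing band centers in nm.
    mode : str
        One of ``FL``, ``VISNIR``, ``SWIR``.
    exposure_ms : float
        Integration time; intensities are assumed linear in it.
    white_frame, dark_frame : ndarray or None
        Per-pixel-per-band reference frames for reflectance calibration.
    saturation_ceiling : float or None
        Detector full-scale value; no stored intensity may exceed it.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    mode: str
    exposure_ms: float = 300.0
    white_frame: np.ndarray | None = None
    dark_frame: np.ndarray | None = None
    saturation_ceiling: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[2]} bands"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if self.saturation_ceiling is not None and np.any(
            self.data > self.saturation_ceiling
        ):
            raise ValueError("intensities exceed the saturation ceiling")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


#: metadata columns of a VoxelTable CSV, in order, before the band columns
VOXEL_META_COLUMNS = [
    "voxel_id",
    "fillet_id",
    "species",
    "day",
    "region",
    "block_row",
    "block_col",
    "kept",
]


@dataclass
class VoxelTable:
    """Per-voxel mean spectra with labels: the unit record for all ML.

    ``frame`` holds one row per voxel with the metadata columns of
    :data:`VOXEL_META_COLUMNS` followed by one column per band named by
    its wavelength.  Rows with ``kept == False`` are excluded from every
    downstream fit.
    """

    frame: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        missing = [c for c in VOXEL_META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"voxel table missing columns {missing}")

    @property
    def band_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in VOXEL_META_COLUMNS]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([float(c) for c in self.band_columns])

    def spectra(self, kept_only: bool = True) -> np.ndarray:
        """Spectra as an (n_voxels, n_bands) array."""
        f = self.frame[self.frame["kept"]] if kept_only else self.frame
        return f[self.band_columns].to_numpy(dtype=float)

    def days(self, kept_only: bool = True) -> np.ndarray:
        f = self.frame[self.frame["kept"]] if kept_only else self.frame
        return f["day"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mode: str) -> "VoxelTable":
        frame = pd.read_csv(path)
        frame["kept"] = frame["kept"].astype(bool)
        return cls(frame=frame, mode=mode)


def make_voxel_frame(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    *,
    fillet_id="f1",
    species: str = "sablefish",
    day=0,
    region: str = "head_top",
    block_coords=None,
    kept=None,
    start_id: int = 0,
) -> pd.DataFrame:
    """Assemble a VoxelTable-shaped DataFrame from an (n, bands) array."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    n = spectra.shape[0]
    if block_coords is None:
        block_coords = [(0, 0)] * n
    if kept is None:
        kept = np.ones(n, dtype=bool)
    meta = pd.DataFrame(
        {
            "voxel_id": np.arange(start_id, start_id + n),
            "fillet_id": np.repeat(fillet_id, n),
            "species": np.repeat(species, n),
            "day": np.repeat(day, n),
            "region": np.repeat(region, n),
            "block_row": [bc[0] for bc in block_coords],
            "block_col": [bc[1] for bc in block_coords],
            "kept": np.asarray(kept, dtype=bool),
        }
    )
    bands = pd.DataFrame(spectra, columns=[f"{w:.1f}" for w in wavelengths])
    return pd.concat([meta, bands.set_index(meta.index)], axis=1)
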