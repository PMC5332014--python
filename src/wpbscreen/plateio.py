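"""Plate formats, naming conventions and configuration.

File conventions:

* field images: single-channel TIFF named
  ``<row><col(2-digit)>_f<field>_ch<channel>.tif`` under a plate directory
  (channel 1 = nuclei, 2 = WPB/vWF by default);
* result tables: comma-separated CSV with a header row, UTF-8, '.' decimal;
* screen inputs: the classic 3-column format (plate id, well id, value),
  tab-separated without a header, one file per plate per feature, under
  folders ``1_PercentWPBarea`` .. ``4_TotalFoVpercentWPBnr``;
* plate list and plate-configuration (well roles) files as simple TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InputError, ParameterError

__all__ = [
    "parse_well_id",
    "format_well_id",
    "all_wells",
    "PipelineConfig",
    "PlateManifest",
    "write_field_tiffs",
    "read_feature_file",
    "write_feature_file",
    "write_plate_conf",
    "read_plate_conf",
]

_WELL_RE = re.compile(r"^([A-H])(0[1-9]|1[0-2])$")
_FILE_RE = re.compile(r"^([A-H]\d{2})_f(\d+)_ch(\d+)\.tiff?$")


def parse_well_id(text: str) -> tuple[int, int]:
    """Parse a strict 96-well identifier: 'A01' -> (0, 0), 'H12' -> (7, 11)."""
    m = _WELL_RE.match(str(text))
    if not m:
        raise InputError(f"malformed well identifier: {text!r}")
    return ord(m.group(1)) - ord("A"), int(m.group(2)) - 1


def format_well_id(row: int, col: int) -> str:
    """Inverse of :func:`parse_well_id`: (0, 0) -> 'A01'."""
    if not (0 <= row < 8 and 0 <= col < 12):
        raise ParameterError(f"well position out of range: ({row}, {col})")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def all_wells() -> list[str]:
    """The 96 well identifiers in row-major order (A01 .. H12)."""
    return [format_well_id(r, c) for r in range(8) for c in range(12)]


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with screen defaults.

    ``bernsen_contrast`` is the single parameter that routinely needs
    adjustment: raise it from 15 to 30 or 50 when the vWF stain is weak
    and background pixels start being detected. ``cellcount_mode``
    selects how cells per field are counted for the per-cell features:
    'zones' (default; number of influence zones, i.e. all nuclei) or
    'wpb_cells' (legacy; only cells containing at least one WPB).
    """

    pixel_size_um: float = 0.1615
    median_radius_px: int = 2
    nucleus_area_bounds_um2: tuple[float, float] = (50.0, 2500.0)
    bernsen_window_radius_px: int = 15
    bernsen_contrast: float = 15.0
    rolling_ball_radius_px: int = 1
    wpb_max_area_um2: float = 10.0
    feret_cut_um: float = 1.5
    z_threshold: float = 2.0
    cellcount_mode: str = "zones"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cellcount_mode not in ("zones", "wpb_cells"):
            raise ParameterError(
                f"cellcount_mode must be 'zones' or 'wpb_cells', got {self.cellcount_mode!r}"
            )
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel size must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "nucleus_area_bounds_um2" in data:
            data["nucleus_area_bounds_um2"] = tuple(data["nucleus_area_bounds_um2"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["nucleus_area_bounds_um2"] = list(d["nucleus_area_bounds_um2"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PlateManifest:
    """Index of a plate's field images on disk.

    ``files[(well, field, channel)] -> Path``; the channel map names the
    roles ('nuclei' and 'wpb' are required, others optional).
    """

    plate_id: str
    plate_dir: Path
    files: dict
    channel_map: dict = field(default_factory=lambda: {"nuclei": 1, "wpb": 2})
    pixel_size_um: float = 0.1615

    @classmethod
    def discover(
        cls,
        plate_dir,
        plate_id: str | None = None,
        channel_map: dict | None = None,
        pixel_size_um: float = 0.1615,
    ) -> "PlateManifest":
        """Build a manifest by filename pattern from a plate directory."""
        plate_dir = Path(plate_dir)
        if not plate_dir.is_dir():
            raise InputError(f"plate directory not found: {plate_dir}")
        files = {}
        for p in sorted(plate_dir.iterdir()):
            m = _FILE_RE.match(p.name)
            if m:
                well, fov, ch = m.group(1), int(m.group(2)), int(m.group(3))
                parse_well_id(well)
                files[(well, fov, ch)] = p
        if not files:
            raise InputError(f"no field images matching the naming pattern in {plate_dir}")
        manifest = cls(
            plate_id=plate_id or plate_dir.name,
            plate_dir=plate_dir,
            files=files,
            channel_map=channel_map or {"nuclei": 1, "wpb": 2},
            pixel_size_um=pixel_size_um,
        )
        manifest.validate()
        return manifest

    def validate(self) -> None:
        for role in ("nuclei", "wpb"):
            if role not in self.channel_map:
                raise InputError(f"channel map lacks the required {role!r} role")
        for (well, fov, _ch), path in self.files.items():
            if not Path(path).exists():
                raise InputError(f"missing file: {path}")
        for well, fov in self.well_fields():
            for role in ("nuclei", "wpb"):
                if (well, fov, self.channel_map[role]) not in self.files:
                    raise InputError(
                        f"well {well} field {fov} lacks the {role} channel"
                    )

    def well_fields(self) -> list[tuple[str, int]]:
        return sorted({(w, f) for (w, f, _c) in self.files})

    def load(self, well: str, fov: int, role: str) -> np.ndarray:
        path = self.files[(well, fov, self.channel_map[role])]
        img = tifffile.imread(path)
        if img.ndim != 2:
            raise InputError(f"{path} is not a single-channel 2-D image")
        return img


def write_field_tiffs(plate_dir, well: str, fov: int, channels: dict) -> None:
    """Write ``{channel_index: image}`` as the per-field TIFF files."""
    plate_dir = Path(plate_dir)
    plate_dir.mkdir(parents=True, exist_ok=True)
    for ch, img in channels.items():
        tifffile.imwrite(plate_dir / f"{well}_f{fov}_ch{ch}.tif", img)


def write_feature_file(path, plate_id: str, wells: list[str], values) -> None:
    """Write one 3-column screen file (plate, well, value; TSV, no header)."""
    df = pd.DataFrame({"plate": plate_id, "well": wells, "value": values})
    df.to_csv(path, sep="\t", header=False, index=False)


def read_feature_file(path) -> pd.DataFrame:
    """Read a 3-column screen file into columns (plate, well, value)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["plate", "well", "value"])
    for w in df["well"]:
        parse_well_id(w)
    return df


def write_plate_conf(path, well_roles: dict) -> None:
    """Plate-configuration TSV: columns Well, Content."""
    df = pd.DataFrame(
        {"Well": list(well_roles), "Content": [well_roles[w] for w in well_roles]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_plate_conf(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    if not {"Well", "Content"} <= set(df.columns):
        raise InputError(f"plate configuration {path} needs Well and Content columns")
    return dict(zip(df["Well"], df["Content"]))
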