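"""Reading and writing of external artifacts.

Covers 8-bit RGB frame sequences (numbered image files or video containers),
CVAT "annotations 1.1" point-track XML, plain-text calibration point pairs,
and the key=value run configuration. Coordinates everywhere are 0-based with
``x`` the pixel column and ``y`` the pixel row; CVAT points are consumed
verbatim since CVAT uses the same convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
from lxml import etree

__all__ = [
    "FrameImage",
    "LandmarkPoint",
    "LandmarkTrack",
    "AnnotationSet",
    "RunConfig",
    "ConfigError",
    "AnnotationError",
    "GATE_THRESHOLDS",
    "read_frames",
    "read_cvat_xml",
    "write_cvat_xml",
    "load_config",
    "read_calibration_pairs",
    "write_calibration_pairs",
]

# Quality-gate thresholds on the mean Hamming matching distance, per detector.
# Calibrated so that a passing match set corresponds to a RANSAC inlier ratio
# of about 0.6 at the 5 px reprojection threshold.
GATE_THRESHOLDS = {"ORB1000": 35.0, "AKAZE": 55.0, "BRISK": 65.0}

DETECTORS = ("ORB1000", "AKAZE", "BRISK")
DESCRIPTORS = ("native", "BEBLID256", "BEBLID512")
TRANSFORMS = ("SH", "HMA", "MLS")


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation data."""


@dataclass(frozen=True)
class FrameImage:
    """One 8-bit RGB video frame with its position in the sequence."""

    pixels: np.ndarray  # (H, W, 3) uint8
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"frame must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"frame smaller than 8x8: {px.shape[:2]}")
        if px.dtype != np.uint8:
            raise ValueError(f"frame must be uint8, got {px.dtype}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the frame."""
        return self.pixels.shape[:2]


class LandmarkPoint(NamedTuple):
    x: float
    y: float
    visible: bool


@dataclass
class LandmarkTrack:
    """Per-frame position and visibility of one annotated ground-truth point."""

    track_id: int
    points: dict[int, LandmarkPoint] = field(default_factory=dict)

    def visible_frames(self) -> list[int]:
        return sorted(f for f, p in self.points.items() if p.visible)


@dataclass
class AnnotationSet:
    """All landmark tracks of one annotated scene."""

    tracks: list[LandmarkTrack]
    n_frames: int
    image_size: tuple[int, int]  # (W, H)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise AnnotationError("track ids must be unique")
        for t in self.tracks:
            if not t.points:
                raise AnnotationError(f"track {t.track_id} has no points")
            for f in t.points:
                if not 0 <= f < self.n_frames:
                    raise AnnotationError(
                        f"track {t.track_id}: frame {f} outside [0, {self.n_frames - 1}]"
                    )

    def visible_points(self, frame: int) -> dict[int, tuple[float, float]]:
        """track_id -> (x, y) for landmarks visible in ``frame``."""
        out = {}
        for t in self.tracks:
            p = t.points.get(frame)
            if p is not None and p.visible:
                out[t.track_id] = (p.x, p.y)
        return out

    def covisible_pairs(
        self, frame_a: int, frame_b: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ids, points_a, points_b) for landmarks visible in both frames."""
        pa = self.visible_points(frame_a)
        pb = self.visible_points(frame_b)
        ids = sorted(set(pa) & set(pb))
        a = np.array([pa[i] for i in ids], float).reshape(-1, 2)
        b = np.array([pb[i] for i in ids], float).reshape(-1, 2)
        return np.array(ids, int), a, b

    def mean_visible_per_frame(self) -> float:
        counts = np.zeros(self.n_frames)
        for t in self.tracks:
            for f, p in t.points.items():
                if p.visible:
                    counts[f] += 1
        return float(counts.mean())


@dataclass
class RunConfig:
    """All tunable parameters of the registration pipeline with their defaults."""

    detector: str = "ORB1000"
    descriptor: str = "native"
    transform: str = "SH"
    seed: int = 17
    frame_index_base: int = 0
    start_frames: tuple[int, ...] = (20, 200, 400, 600)
    last_frame: int = 749
    # preprocessing
    glare_lower_frac: float = 0.20
    glare_upper_frac: float = 0.80
    glare_mode: str = "range"  # range | percentile
    box_size: int = 5
    clahe_tiles: int = 8
    clahe_clip: float = 2.0
    # matching / gate
    match_retain_frac: float = 0.20
    gate_threshold: float | None = None  # None -> detector default
    # estimation
    ransac_threshold: float = 5.0
    ransac_max_trials: int = 2000
    ransac_confidence: float = 0.995
    hma_split_ratio: float = 0.5
    hma_min_region: int = 4
    hma_k_min: int = 2
    hma_k_max: int = 10
    hma_k_divisor: int = 50
    mls_grid_density: float = 0.2
    mls_alpha: float = 1.0
    # fusion / postprocessing
    region_min_area_frac: float = 0.02
    region_h_diff_max: float = 50.0
    closing_size: int = 35
    error_threshold_frac: float = 0.10
    median_size: int = 35
    diff_on_equalized: bool = False
    # evaluation / overlay
    ssim_fill: str = "mean"  # mean | zero | current
    nre_zero_motion: str = "exclude"  # exclude | epsilon
    overlay_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.detector not in DETECTORS:
            raise ConfigError(f"unknown detector {self.detector!r}")
        if self.descriptor not in DESCRIPTORS:
            raise ConfigError(f"unknown descriptor {self.descriptor!r}")
        if self.transform not in TRANSFORMS:
            raise ConfigError(f"unknown transform {self.transform!r}")
        for name in (
            "box_size",
            "clahe_tiles",
            "match_retain_frac",
            "ransac_threshold",
            "mls_grid_density",
            "closing_size",
            "median_size",
            "region_h_diff_max",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def effective_gate_threshold(self) -> float:
        """Explicit gate threshold, else the detector's calibrated default."""
        if self.gate_threshold is not None:
            return self.gate_threshold
        return GATE_THRESHOLDS[self.detector]


# ---------------------------------------------------------------------------
# frames


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path) -> tuple:
    m = _NUM_RE.findall(p.stem)
    return (int(m[-1]),) if m else (p.stem,)


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def read_frames(source: str | Path, indices: list[int] | None = None) -> list[FrameImage]:
    """Read frames from a directory of numbered images or a video container.

    Frames are returned in ascending index order. ``indices`` selects a
    subset by 0-based sequence position; ``None`` reads everything.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    if indices is not None:
        indices = sorted(set(int(i) for i in indices))
        if indices and indices[0] < 0:
            raise IndexError(f"negative frame index {indices[0]}")
        if not indices:
            return []
    if source.is_dir():
        files = sorted(
            (p for p in source.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}),
            key=_numeric_key,
        )
        if indices is None:
            indices = list(range(len(files)))
        if indices and indices[-1] >= len(files):
            raise IndexError(f"frame index {indices[-1]} beyond sequence of {len(files)}")
        return [FrameImage(_as_rgb(iio.imread(files[i])), frame_index=i) for i in indices]
    # video container path: delegate decoding to imageio
    frames = []
    want = set(indices) if indices is not None else None
    last = -1
    for i, arr in enumerate(iio.imiter(source)):
        last = i
        if want is None or i in want:
            frames.append(FrameImage(_as_rgb(arr), frame_index=i))
        if want is not None and i >= max(want):
            break
    if want is not None and max(want) > last:
        raise IndexError(f"frame index {max(want)} beyond sequence of {last + 1}")
    return frames


# ---------------------------------------------------------------------------
# CVAT XML


def read_cvat_xml(path: str | Path) -> AnnotationSet:
    """Parse a CVAT "annotations 1.1" XML file with point tracks.

    A point is invisible when CVAT marks it ``outside`` OR ``occluded``
    (annotation exports differ in which flag they use; both are honored).
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise AnnotationError(f"malformed CVAT XML: {e}") from e
    root = tree.getroot()

    n_frames = 0
    width = height = 0
    size_el = root.find(".//meta//size")
    if size_el is not None and size_el.text and size_el.text.strip().isdigit():
        n_frames = int(size_el.text.strip())
    w_el = root.find(".//meta//original_size/width")
    h_el = root.find(".//meta//original_size/height")
    if w_el is not None and h_el is not None:
        width, height = int(w_el.text), int(h_el.text)

    tracks: list[LandmarkTrack] = []
    for tr in root.iter("track"):
        tid = int(tr.get("id"))
        points: dict[int, LandmarkPoint] = {}
        for el in tr:
            if el.tag not in ("points", "point"):
                continue
            frame = int(el.get("frame"))
            coords = el.get("points", "")
            xy = coords.split(";")[0].split(",")
            if len(xy) != 2:
                raise AnnotationError(f"track {tid}, frame {frame}: bad points attribute {coords!r}")
            x, y = float(xy[0]), float(xy[1])
            outside = el.get("outside", "0") == "1"
            occluded = el.get("occluded", "0") == "1"
            points[frame] = LandmarkPoint(x, y, visible=not (outside or occluded))
        if not points:
            raise AnnotationError(f"track {tid} has no points")
        tracks.append(LandmarkTrack(tid, points))

    if n_frames == 0:
        n_frames = 1 + max((f for t in tracks for f in t.points), default=-1)
    if width == 0 or height == 0:
        xs = [p.x for t in tracks for p in t.points.values()]
        ys = [p.y for t in tracks for p in t.points.values()]
        width = int(np.ceil(max(xs, default=0))) + 1
        height = int(np.ceil(max(ys, default=0))) + 1
    return AnnotationSet(tracks=tracks, n_frames=n_frames, image_size=(width, height))


def write_cvat_xml(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as CVAT "annotations 1.1" point tracks.

    ``read_cvat_xml(write_cvat_xml(a))`` reproduces ``a`` with coordinates
    preserved to better than 1e-3 px.
    """
    root = etree.Element("annotations")
    etree.SubElement(root, "version").text = "1.1"
    meta = etree.SubElement(root, "meta")
    task = etree.SubElement(meta, "task")
    etree.SubElement(task, "size").text = str(annotations.n_frames)
    osize = etree.SubElement(task, "original_size")
    etree.SubElement(osize, "width").text = str(annotations.image_size[0])
    etree.SubElement(osize, "height").text = str(annotations.image_size[1])
    for t in annotations.tracks:
        tr = etree.SubElement(root, "track", id=str(t.track_id), label="landmark", source="manual")
        for frame in sorted(t.points):
            p = t.points[frame]
            etree.SubElement(
                tr,
                "points",
                frame=str(frame),
                points=f"{p.x:.4f},{p.y:.4f}",
                outside="0" if p.visible else "1",
                occluded="0",
                keyframe="1",
            )
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# calibration point pairs (x_src,y_src,x_dst,y_dst CSV)


def read_calibration_pairs(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read (src, dst) point pairs from a 4-column CSV with header."""
    data = np.genfromtxt(str(path), delimiter=",", names=True)
    src = np.column_stack([data["x_src"], data["y_src"]]).astype(float)
    dst = np.column_stack([data["x_dst"], data["y_dst"]]).astype(float)
    return src, dst


def write_calibration_pairs(src: np.ndarray, dst: np.ndarray, path: str | Path) -> None:
    arr = np.column_stack([src, dst])
    np.savetxt(str(path), arr, delimiter=",", header="x_src,y_src,x_dst,y_dst", comments="")


# ---------------------------------------------------------------------------
# run configuration


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_value(name: str, raw: str, type_name: str):
    raw = raw.strip()
    try:
        if type_name == "bool":
            return _BOOL[raw.lower()]
        if type_name == "int":
            return int(raw)
        if type_name == "float":
            return float(raw)
        if "None" in type_name:  # optional float (gate_threshold)
            return None if raw.lower() == "none" else float(raw)
        if type_name.startswith("tuple"):
            return tuple(int(v) for v in raw.replace(",", " ").split())
        return raw
    except (KeyError, ValueError) as e:
        raise ConfigError(f"cannot parse value {raw!r} for key {name!r}") from e


def load_config(path: str | Path) -> RunConfig:
    """Load a key=value config file; unspecified keys keep pipeline defaults.

    Lines starting with ``#`` and blank lines are ignored. Unknown keys are a
    hard error naming the key, so typos never silently fall back to defaults.
    """
    known = {f.name: f.type for f in fields(RunConfig)}
    overrides = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        overrides[key] = _parse_value(key, raw, str(known[key]))
    return replace(RunConfig(), **overrides)
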