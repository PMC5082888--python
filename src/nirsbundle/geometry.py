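"""Bundled-optode probe geometry.

A *bundle* groups one emitter with one short-separation detector (5 mm,
sampling mainly scalp) and several long-separation detectors (roughly
12–45 mm, sampling progressively deeper cortex).  Each long detector,
paired with the bundle's short channel, forms one *gradient channel*: the
spatial absorbance gradient between the two emitter–detector pairs is what
the optics module inverts into absolute hemoglobin concentrations.

All distances are stored in millimetres.  The default montage places
32 optodes (8 emitters, 24 detectors) on a planar 40 mm x 15 mm scalp
patch over the motor cortex, yielding 8 bundles and 48 gradient channels.
The patch is a topological reconstruction of the published arrangement;
exact within-patch spacings are a documented package choice (see
docs/methods.md).  Coordinates are planar-scalp approximations; no
head-surface registration is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .errors import ConfigError, GeometryError

#: Nominal emitter-detector separations (mm) of a full one-emitter,
#: seven-detector bundle: one short channel at 5 mm and six long channels.
#: The sixth long separation (45 mm) extends the published 15/25/30/35/40 mm
#: list so that a full bundle yields six gradient channels.
NOMINAL_SEPARATIONS_MM = (5.0, 15.0, 25.0, 30.0, 35.0, 40.0, 45.0)


@dataclass(frozen=True)
class Optode:
    """A single emitter or detector fiber on the scalp."""

    id: int
    role: str  # "emitter" | "detector"
    position: tuple[float, float]  # (x, y) mm

    def __post_init__(self) -> None:
        if self.role not in ("emitter", "detector"):
            raise GeometryError(f"optode {self.id}: unknown role {self.role!r}")
        if not all(math.isfinite(c) for c in self.position):
            raise GeometryError(f"optode {self.id}: non-finite position")


def _dist(a: Optode, b: Optode) -> float:
    (x1, y1), (x2, y2) = a.position, b.position
    return math.hypot(x1 - x2, y1 - y2)


@dataclass(frozen=True)
class Bundle:
    """One emitter with its short-separation and long-separation detectors."""

    id: int
    emitter: Optode
    short_detector: Optode
    long_detectors: tuple[Optode, ...]

    def __post_init__(self) -> None:
        if not self.long_detectors:
            raise GeometryError(f"bundle {self.id}: needs at least one long detector")
        short = self.short_separation
        if short <= 0:
            raise GeometryError(f"bundle {self.id}: non-positive short separation")
        for det in self.long_detectors:
            sep = _dist(self.emitter, det)
            if sep <= 0:
                raise GeometryError(
                    f"bundle {self.id}: non-positive separation to detector {det.id}"
                )
            if sep <= short:
                raise GeometryError(
                    f"bundle {self.id}: long separation {sep:.3g} mm to detector "
                    f"{det.id} does not exceed short separation {short:.3g} mm"
                )

    @property
    def short_separation(self) -> float:
        """Emitter to short-detector distance (mm)."""
        return _dist(self.emitter, self.short_detector)

    @property
    def long_separations(self) -> tuple[float, ...]:
        return tuple(_dist(self.emitter, d) for d in self.long_detectors)

    @property
    def short_pair_label(self) -> str:
        """Label of the physical short-separation emitter-detector pair."""
        return f"B{self.id}S"


@dataclass(frozen=True)
class Channel:
    """A gradient channel: one long pair referenced to its bundle's short pair.

    ``distance_l`` is the emitter-to-long-detector distance l; ``delta_l`` is
    the separation difference versus the bundle's short channel, the spatial
    baseline of the absorbance gradient.  ``coordinate3d`` places the channel
    at the emitter-detector midpoint with depth equal to half the separation
    (the apex of the banana-shaped photon path).
    """

    id: int
    bundle_id: int
    emitter: Optode
    detector: Optode
    distance_l: float
    delta_l: float
    coordinate3d: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.distance_l <= 0:
            raise GeometryError(f"channel {self.id}: distance_l must be > 0")
        if self.delta_l < 0:
            raise GeometryError(f"channel {self.id}: delta_l must be >= 0")
        if self.coordinate3d[2] < 0:
            raise GeometryError(f"channel {self.id}: negative depth")

    @property
    def pair_label(self) -> str:
        """Label of the physical long-separation emitter-detector pair."""
        return f"C{self.id}"


@dataclass
class ProbeLayout:
    """A full montage: optodes, bundles, and the derived gradient channels."""

    optodes: list[Optode] = field(default_factory=list)
    bundles: list[Bundle] = field(default_factory=list)
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [o.id for o in self.optodes]
        if len(ids) != len(set(ids)):
            raise GeometryError("duplicate optode ids in layout")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def emitters(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "emitter"]

    @property
    def detectors(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "detector"]

    def bundle_of(self, channel: Channel) -> Bundle:
        for b in self.bundles:
            if b.id == channel.bundle_id:
                return b
        raise GeometryError(f"channel {channel.id}: unknown bundle {channel.bundle_id}")

    def pair_labels(self) -> list[str]:
        """All physical emitter-detector pair labels (short pairs first)."""
        return [b.short_pair_label for b in self.bundles] + [
            c.pair_label for c in self.channels
        ]


def channel_coordinate(
    emitter_pos: Sequence[float], detector_pos: Sequence[float]
) -> tuple[float, float, float]:
    """3D target coordinate of an emitter-detector pair.

    The probed volume is centred under the midpoint of the pair, at a depth
    of half the separation: (x, y, z) = ((x1+x2)/2, (y1+y2)/2,
    sqrt((x1-x2)^2 + (y1-y2)^2)/2).  Symmetric in its two arguments.  A
    coincident pair is degenerate (z = 0) but permitted.
    """
    (x1, y1), (x2, y2) = emitter_pos, detector_pos
    if not all(math.isfinite(v) for v in (x1, y1, x2, y2)):
        raise GeometryError("non-finite optode position")
    return ((x1 + x2) / 2.0, (y1 + y2) / 2.0, math.hypot(x1 - x2, y1 - y2) / 2.0)


def channel_sampling_offset(
    n_optodes: int, frame_rate_hz: float, rounded: bool = True
) -> float:
    """Acquisition-time offset between two neighboring channels, in ms.

    A frame scans all optodes sequentially, so neighboring channels are
    sampled 1/(frame_rate x n_optodes) apart.  With 32 optodes at 1.81 Hz
    this is ~17 ms, small enough that the attenuation coefficient can be
    treated as common to neighboring channels.
    """
    if n_optodes < 1:
        raise ConfigError("n_optodes must be >= 1")
    if frame_rate_hz <= 0:
        raise ConfigError("frame_rate_hz must be > 0")
    ms = 1000.0 / (frame_rate_hz * n_optodes)
    return float(round(ms)) if rounded else ms


def build_bundle(emitter: Optode, detectors: Sequence[Optode], bundle_id: int = 1) -> Bundle:
    """Group an emitter with detectors; the first detector is the short one.

    A bundle with n detectors yields n-1 gradient channels (e.g. 7 detectors
    give 6 gradients), so at least two detectors are required.
    """
    if len(detectors) < 2:
        raise GeometryError("a bundle needs >= 2 detectors (1 short + >=1 long)")
    return Bundle(
        id=bundle_id,
        emitter=emitter,
        short_detector=detectors[0],
        long_detectors=tuple(detectors[1:]),
    )


def _bundle_channels(bundle: Bundle, first_channel_id: int) -> list[Channel]:
    """Gradient channels of a bundle, distance-ascending, ids consecutive."""
    short_sep = bundle.short_separation
    dets = sorted(bundle.long_detectors, key=lambda d: _dist(bundle.emitter, d))
    out = []
    for k, det in enumerate(dets):
        l_long = _dist(bundle.emitter, det)
        out.append(
            Channel(
                id=first_channel_id + k,
                bundle_id=bundle.id,
                emitter=bundle.emitter,
                detector=det,
                distance_l=l_long,
                delta_l=abs(l_long - short_sep),
                coordinate3d=channel_coordinate(bundle.emitter.position, det.position),
            )
        )
    return out


def build_montage(config: dict) -> ProbeLayout:
    """Build a :class:`ProbeLayout` from a config mapping.

    ``config`` has two keys: ``optodes`` — a list of ``{id, role, x, y}``
    mappings (mm) — and ``bundles`` — a list of ``{emitter, detectors}``
    where ``detectors`` is an ordered list of optode ids whose first entry
    is the short-separation detector.  Channel ids are assigned
    bundle-major, distance-ascending, starting at 1.
    """
    optodes: dict[int, Optode] = {}
    for entry in config.get("optodes", []):
        opt = Optode(
            id=int(entry["id"]),
            role=str(entry["role"]),
            position=(float(entry["x"]), float(entry["y"])),
        )
        if opt.id in optodes:
            raise GeometryError(f"duplicate optode id {opt.id}")
        optodes[opt.id] = opt

    bundles: list[Bundle] = []
    channels: list[Channel] = []
    next_id = 1
    for k, entry in enumerate(config.get("bundles", []), start=1):
        try:
            emitter = optodes[int(entry["emitter"])]
            dets = [optodes[int(d)] for d in entry["detectors"]]
        except KeyError as exc:
            raise GeometryError(f"bundle {k}: unknown optode {exc}") from None
        bundle = build_bundle(emitter, dets, bundle_id=k)
        bundles.append(bundle)
        chans = _bundle_channels(bundle, next_id)
        channels.extend(chans)
        next_id += len(chans)

    return ProbeLayout(optodes=list(optodes.values()), bundles=bundles, channels=channels)


def default_layout_config() -> dict:
    """Config of the default 32-optode motor-cortex patch.

    Four parallel rows 5 mm apart; each row holds two inward-facing emitters
    at its ends (x = 0 and 40 mm) and six shared detectors at x = 5, 12.5,
    17.5, 22.5, 27.5 and 35 mm.  Each emitter's nearest detector (5 mm) is
    its short-separation detector; the five remaining row detectors plus one
    detector borrowed from the paired row (rows 1-2 and 3-4 pair up) are its
    six long detectors.  Totals: 8 emitters + 24 detectors = 32 optodes,
    8 bundles, 48 gradient channels.
    """
    det_x = (5.0, 12.5, 17.5, 22.5, 27.5, 35.0)
    optodes = []
    rows: list[dict[str, object]] = []
    next_id = 1
    for r in range(4):
        y = 5.0 * r
        left = next_id
        optodes.append({"id": left, "role": "emitter", "x": 0.0, "y": y})
        det_ids = []
        for j, x in enumerate(det_x):
            did = next_id + 1 + j
            optodes.append({"id": did, "role": "detector", "x": x, "y": y})
            det_ids.append(did)
        right = next_id + 7
        optodes.append({"id": right, "role": "emitter", "x": 40.0, "y": y})
        rows.append({"left": left, "right": right, "dets": det_ids})
        next_id += 8

    bundles = []
    for r, row in enumerate(rows):
        partner = rows[r + 1 if r % 2 == 0 else r - 1]
        dets = row["dets"]  # ascending x: nearest-to-left first
        # left emitter at x=0: short at x=5; borrow partner-row far detector x=35
        bundles.append(
            {"emitter": row["left"], "detectors": list(dets) + [partner["dets"][5]]}
        )
        # right emitter at x=40: short at x=35; borrow partner-row x=5
        bundles.append(
            {
                "emitter": row["right"],
                "detectors": list(reversed(dets)) + [partner["dets"][0]],
            }
        )
    return {"optodes": optodes, "bundles": bundles}


def default_layout() -> ProbeLayout:
    """The default 8-bundle, 48-channel montage (see default_layout_config)."""
    return build_montage(default_layout_config())


def line_bundle_layout(
    separations_mm: Iterable[float] = NOMINAL_SEPARATIONS_MM,
) -> ProbeLayout:
    """A single collinear bundle with exact nominal separations.

    One emitter at the origin and detectors along +x at the given distances
    (first = short).  The full default of 7 detectors yields 6 gradient
    channels; useful for controlled simulations and worked examples.
    """
    seps = list(separations_mm)
    optodes = [{"id": 1, "role": "emitter", "x": 0.0, "y": 0.0}]
    for j, s in enumerate(seps, start=2):
        optodes.append({"id": j, "role": "detector", "x": float(s), "y": 0.0})
    return build_montage(
        {"optodes": optodes, "bundles": [{"emitter": 1, "detectors": list(range(2, len(seps) + 2))}]}
    )


# ---------------------------------------------------------------------------
# I/O helpers

def layout_to_config(layout: ProbeLayout) -> dict:
    """Serializable config reproducing ``layout`` via :func:`build_montage`."""
    optodes = [
        {"id": o.id, "role": o.role, "x": o.position[0], "y": o.position[1]}
        for o in layout.optodes
    ]
    bundles = []
    for b in layout.bundles:
        bundles.append(
            {
                "emitter": b.emitter.id,
                "detectors": [b.short_detector.id] + [d.id for d in b.long_detectors],
            }
        )
    return {"optodes": optodes, "bundles": bundles}


def write_layout_yaml(layout: ProbeLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_to_config(layout), fh, sort_keys=False)


def read_layout_yaml(path) -> ProbeLayout:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "optodes" not in cfg:
        raise ConfigError(f"{path}: not a layout config")
    return build_montage(cfg)


def channel_table(layout: ProbeLayout):
    """Channel geometry as a tidy DataFrame (exported as TSV by the CLI)."""
    import pandas as pd

    rows = []
    for c in layout.channels:
        x, y, z = c.coordinate3d
        rows.append(
            {
                "channel": c.id,
                "bundle": c.bundle_id,
                "emitter": c.emitter.id,
                "detector": c.detector.id,
                "l_mm": c.distance_l,
                "delta_l_mm": c.delta_l,
                "x_mm": x,
                "y_mm": y,
                "z_mm": z,
            }
        )
    return pd.DataFrame(rows)
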