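"""Readers and writers for models, gait kinematics and mapping tables.

Supported formats
-----------------
* native model files: YAML/JSON documents with top-level keys ``species``,
  ``segments``, ``joints``, ``muscles`` (schema in ``docs/model_format.md``);
  lengths may be authored in mm (``units: {length: mm}``), angles are
  always degrees on file and radians in memory;
* OpenSim ``.osim`` XML, read-only subset: muscle parameters and fixed
  path points; wrap objects and conditional/moving path points are skipped
  with a warning and the unit flagged ``geometry_approximate``;
* OpenSim ``.mot``/``.sto`` motion files (tab-delimited, ``endheader``
  sentinel) and plain CSV kinematics; trajectories are resampled onto the
  uniform 101-point gait grid, and toe-off-start cycles are rotated so the
  cycle begins at heel strike;
* homolog-map CSV (columns ``mouse, human, group``) and fat-fraction CSV
  (columns ``muscle, fraction, group``).
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .geometry import LengthSurface
from .model import (
    GAIT_GRID,
    HomologMap,
    Joint,
    JointKinematics,
    ModelValidationError,
    MuscleTendonUnit,
    MusculoskeletalModel,
    PathPoint,
    Segment,
)

__all__ = [
    "read_model",
    "write_model",
    "read_kinematics",
    "write_kinematics_csv",
    "read_homolog_map",
    "read_fat_fraction",
]


# ---------------------------------------------------------------------------
# native model format
# ---------------------------------------------------------------------------

def _native_to_model(doc: dict, source: str) -> MusculoskeletalModel:
    length_scale = 1.0
    units_decl = doc.get("units", {})
    if isinstance(units_decl, dict) and units_decl.get("length", "m") == "mm":
        length_scale = 1e-3

    def vec(v):
        return tuple(float(x) * length_scale for x in v)

    segments = [Segment(name=s) for s in doc.get("segments", [])]
    joints = []
    for j in doc.get("joints", []):
        rng = j.get("range_deg")
        joints.append(
            Joint(
                name=j["name"],
                parent=j["parent"],
                child=j["child"],
                location_in_parent=vec(j.get("location_in_parent", (0, 0, 0))),
                axis=tuple(float(x) for x in j.get("axis", (0, 0, 1))),
                sign=float(j.get("sign", 1.0)),
                default_angle=math.radians(float(j.get("default_angle_deg", 0.0))),
                articulated=bool(j.get("articulated", True)),
                range=(
                    (math.radians(float(rng[0])), math.radians(float(rng[1])))
                    if rng else None
                ),
            )
        )

    units = []
    surfaces = {}
    for m in doc.get("muscles", []):
        muscle_name = m["name"]
        for u in m.get("units", []):
            uname = u.get("name", muscle_name)
            for key in ("F_o", "L_o", "V_max", "L_s"):
                if key not in u:
                    raise ModelValidationError(
                        f"{source}: unit '{uname}' missing required "
                        f"parameter '{key}'"
                    )
            path = [
                PathPoint(segment=p["segment"], location=vec(p["location"]))
                for p in u.get("path", [])
            ]
            backend = "path"
            if "surface" in u:
                backend = "surface"
                surfaces[uname] = LengthSurface.from_dict(
                    {"muscle": uname, **u["surface"]}
                )
            try:
                units.append(
                    MuscleTendonUnit(
                        name=uname,
                        F_o=float(u["F_o"]),
                        L_o=float(u["L_o"]) * length_scale,
                        V_max=float(u["V_max"]),
                        alpha_o=math.radians(float(u.get("alpha_o_deg", 0.0))),
                        L_s=float(u["L_s"]) * length_scale,
                        L_o_sd=(None if u.get("L_o_sd") is None
                                else float(u["L_o_sd"]) * length_scale),
                        L_s_sd=(None if u.get("L_s_sd") is None
                                else float(u["L_s_sd"]) * length_scale),
                        path=path,
                        parent_muscle=muscle_name,
                        geometry_backend=backend,
                    )
                )
            except ModelValidationError as e:
                raise ModelValidationError(f"{source}: {e}") from e

    return MusculoskeletalModel(
        species=doc.get("species", "unknown"),
        segments=segments,
        joints=joints,
        units=units,
        surfaces=surfaces,
        cycle_duration=float(doc.get("cycle_duration", 1.0)),
    )


def _model_to_native(model: MusculoskeletalModel) -> dict:
    joints = []
    for j in model.joints:
        d = {
            "name": j.name,
            "parent": j.parent,
            "child": j.child,
            "location_in_parent": list(j.location_in_parent),
            "axis": list(j.axis),
            "sign": j.sign,
            "default_angle_deg": math.degrees(j.default_angle),
            "articulated": j.articulated,
        }
        if j.range is not None:
            d["range_deg"] = [math.degrees(j.range[0]), math.degrees(j.range[1])]
        joints.append(d)
    muscles = []
    for mname, unit_list in model.muscles.items():
        m = {"name": mname, "units": []}
        for u in unit_list:
            d = {
                "name": u.name,
                "F_o": u.F_o,
                "L_o": u.L_o,
                "V_max": u.V_max,
                "alpha_o_deg": math.degrees(u.alpha_o),
                "L_s": u.L_s,
                **({"L_o_sd": u.L_o_sd} if u.L_o_sd is not None else {}),
                **({"L_s_sd": u.L_s_sd} if u.L_s_sd is not None else {}),
                "path": [
                    {"segment": p.segment, "location": list(p.location)}
                    for p in u.path
                ],
            }
            if u.geometry_backend == "surface":
                s = model.surfaces[u.name].to_dict()
                s.pop("muscle", None)
                d["surface"] = s
            m["units"].append(d)
        muscles.append(m)
    return {
        "format": "myogait-model",
        "units": {"length": "m", "angle": "deg"},
        "species": model.species,
        "cycle_duration": model.cycle_duration,
        "segments": [s.name for s in model.segments],
        "joints": joints,
        "muscles": muscles,
    }


def write_model(model: MusculoskeletalModel, path) -> None:
    """Write a model in the native YAML format (SI lengths, degree angles)."""
    doc = _model_to_native(model)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)


# ---------------------------------------------------------------------------
# OpenSim .osim subset
# ---------------------------------------------------------------------------

_OSIM_REQUIRED = {
    "F_o": "max_isometric_force",
    "L_o": "optimal_fiber_length",
    "L_s": "tendon_slack_length",
}


def _osim_to_model(path: Path) -> MusculoskeletalModel:
    tree = etree.parse(str(path))
    root = tree.getroot()
    model_el = root.find(".//Model")
    if model_el is None:
        raise ModelValidationError(f"{path}: no <Model> element")
    model_warnings: list[str] = []

    def text_of(el, tag):
        child = el.find(tag)
        return None if child is None or child.text is None else child.text.strip()

    # segments: ground + bodies
    segments = [Segment("ground")]
    joints: list[Joint] = []
    for body in model_el.iter("Body"):
        name = body.get("name")
        if name in ("ground",) or name is None:
            continue
        segments.append(Segment(name))
        joint_el = body.find("Joint")
        jdef = None
        if joint_el is not None:
            for sub in joint_el:
                jdef = sub
                break
        if jdef is None:
            continue
        parent = text_of(jdef, "parent_body") or "ground"
        loc = text_of(jdef, "location_in_parent") or "0 0 0"
        location = tuple(float(x) for x in loc.split())
        articulated = jdef.tag == "PinJoint"
        if not articulated:
            model_warnings.append(
                f"joint '{jdef.get('name', name)}' ({jdef.tag}) not a pin "
                "joint; locked at default pose"
            )
        joints.append(
            Joint(
                name=jdef.get("name", f"{name}_joint"),
                parent=parent,
                child=name,
                location_in_parent=location,
                articulated=articulated,
            )
        )

    known_segments = {s.name for s in segments}
    units = []
    for muscle_el in model_el.iter():
        if not isinstance(muscle_el.tag, str) or not muscle_el.tag.endswith("Muscle"):
            continue
        uname = muscle_el.get("name", "unnamed")
        params = {}
        for key, tag in _OSIM_REQUIRED.items():
            val = text_of(muscle_el, tag)
            if val is None:
                raise ModelValidationError(
                    f"{path}: muscle '{uname}' missing <{tag}>"
                )
            params[key] = float(val)
        alpha = text_of(muscle_el, "pennation_angle_at_optimal")
        if alpha is None:
            alpha = text_of(muscle_el, "pennation_angle")
        vmax = text_of(muscle_el, "max_contraction_velocity")
        approximate = False
        pathpoints = []
        for pp in muscle_el.iter():
            if not isinstance(pp.tag, str):
                continue
            if pp.tag == "PathPoint":
                loc = text_of(pp, "location")
                body = text_of(pp, "body") or text_of(pp, "socket_parent_frame")
                if loc is None or body is None:
                    continue
                body = body.split("/")[-1]
                if body not in known_segments:
                    segments.append(Segment(body))
                    known_segments.add(body)
                pathpoints.append(
                    PathPoint(segment=body,
                              location=tuple(float(x) for x in loc.split()))
                )
            elif pp.tag in ("ConditionalPathPoint", "MovingPathPoint"):
                model_warnings.append(
                    f"muscle '{uname}': {pp.tag} skipped; geometry approximate"
                )
                approximate = True
        for wrap in muscle_el.iter("PathWrap"):
            model_warnings.append(
                f"muscle '{uname}': wrap object skipped; geometry approximate"
            )
            approximate = True
        units.append(
            MuscleTendonUnit(
                name=uname,
                F_o=params["F_o"],
                L_o=params["L_o"],
                V_max=float(vmax) if vmax else 10.0,
                alpha_o=float(alpha) if alpha else 0.0,  # radians in .osim
                L_s=params["L_s"],
                path=pathpoints,
                geometry_approximate=approximate,
            )
        )
    for wrap in model_el.iter("WrapObjectSet"):
        if len(wrap):
            model_warnings.append("wrap objects present in model; skipped")

    for w in model_warnings:
        warnings.warn(w, stacklevel=3)
    m = MusculoskeletalModel(
        species=model_el.get("name", "unknown"),
        segments=segments,
        joints=joints,
        units=units,
    )
    m.warnings = model_warnings
    return m


def read_model(path, format: str | None = None) -> MusculoskeletalModel:
    """Read a musculoskeletal model from a native or ``.osim`` file.

    Lengths are converted to meters and angles to radians on load.
    Unsupported ``.osim`` elements are skipped with warnings.
    """
    path = Path(path)
    if format is None:
        format = "osim" if path.suffix.lower() == ".osim" else "native"
    if format == "osim":
        return _osim_to_model(path)
    if format != "native":
        raise ValueError(f"unsupported model format '{format}'")
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ModelValidationError(f"{path}: parse error: {e}") from e
    if not isinstance(doc, dict):
        raise ModelValidationError(f"{path}: expected a mapping at top level")
    return _native_to_model(doc, str(path))


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

_PERCENT_NAMES = ("percent", "gait_percent", "gait_cycle", "percent_gait")


def _read_mot_table(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            start = i + 1
            break
    header = lines[start].split()
    data = [
        [float(x) for x in line.split()]
        for line in lines[start + 1:]
        if line.strip()
    ]
    return pd.DataFrame(data, columns=header)


def _rotate_to_heel_strike(values: np.ndarray, heel_strike_percent: float) -> np.ndarray:
    """Rotate a 101-sample cycle so heel strike (at the given %) becomes 0 %."""
    shift = int(round(heel_strike_percent)) % 100
    core = values[:100]  # sample 100 duplicates sample 0 in a periodic cycle
    rotated = np.roll(core, -shift)
    return np.concatenate([rotated, rotated[:1]])


def read_kinematics(
    path,
    format: str | None = None,
    cycle_convention: str = "heel-strike-start",
    heel_strike_percent: float = 35.0,
    speed: float = float("nan"),
    cycle_duration: float = 1.0,
) -> list[JointKinematics]:
    """Read joint-angle trajectories and normalize them onto the gait grid.

    Angle columns are in degrees.  The time/percent column is detected by
    name; trajectories are linearly resampled to the 101-point 0-100 %
    grid.  For cycles recorded starting at toe-off, ``heel_strike_percent``
    gives the position of heel strike in the recorded cycle and the cycle
    is rotated so it starts at heel strike.

    A CSV with a ``subject`` column yields one :class:`JointKinematics`
    per subject.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in ("mot", "sto", "csv") else "csv"
    if format in ("mot", "sto"):
        df = _read_mot_table(path)
    elif format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    else:
        raise ValueError(f"unsupported kinematics format '{format}'")

    groups: list[tuple[str, pd.DataFrame]]
    if "subject" in df.columns:
        groups = [(str(k), g.drop(columns=["subject"])) for k, g in df.groupby("subject", sort=True)]
    else:
        groups = [(path.stem, df)]

    out = []
    for subject_id, g in groups:
        cols = {c.lower(): c for c in g.columns}
        xcol = None
        for name in _PERCENT_NAMES:
            if name in cols:
                xcol = cols[name]
                is_time = False
                break
        else:
            if "time" in cols:
                xcol = cols["time"]
                is_time = True
        if xcol is None:
            raise ModelValidationError(
                f"{path}: no time or gait-percent column found"
            )
        x = g[xcol].to_numpy(dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ModelValidationError(
                f"{path}: time/percent column not strictly increasing"
            )
        if is_time:
            x = (x - x[0]) / (x[-1] - x[0]) * 100.0
        already_uniform = np.array_equal(x, GAIT_GRID)
        angles = {}
        for c in g.columns:
            if c == xcol:
                continue
            col = g[c].to_numpy(dtype=float)
            # resampling is exactly idempotent on an already-uniform cycle
            y = col.copy() if already_uniform else np.interp(GAIT_GRID, x, col)
            if cycle_convention == "toe-off-start":
                y = _rotate_to_heel_strike(y, heel_strike_percent)
            angles[c] = y
        out.append(
            JointKinematics(
                subject_id=subject_id,
                angles=angles,
                speed=speed,
                cycle_duration=cycle_duration,
                cycle_convention="heel-strike-start",
            )
        )
    return out


def write_kinematics_csv(cohort: list[JointKinematics], path) -> None:
    """Write a cohort of gait cycles to one tidy CSV (``subject`` column)."""
    frames = []
    for kin in cohort:
        d = {"subject": kin.subject_id, "percent": kin.gait_percent}
        d.update({j: kin.angles[j] for j in kin.joints})
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mapping tables
# ---------------------------------------------------------------------------

def read_homolog_map(path) -> HomologMap:
    """Read a mouse-to-human muscle homolog map (CSV: mouse, human, group)."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty homolog map", stacklevel=2)
        return HomologMap(pairs=[])
    for col in ("mouse", "human", "group"):
        if col not in df.columns:
            raise ModelValidationError(f"{path}: missing column '{col}'")
    pairs = list(zip(df["mouse"].astype(str), df["human"].astype(str)))
    if len(set(pairs)) != len(pairs):
        raise ModelValidationError(f"{path}: duplicated homolog pair")
    groups = {p: g for p, g in zip(pairs, df["group"].astype(str))}
    return HomologMap(pairs=pairs, groups=groups)


def read_fat_fraction(path) -> tuple[dict, dict]:
    """Read per-muscle fat fractions (CSV: muscle, fraction, group).

    Returns ``(fractions, groups)`` dictionaries keyed by muscle name.
    """
    df = pd.read_csv(path)
    for col in ("muscle", "fraction", "group"):
        if col not in df.columns:
            raise ModelValidationError(f"{path}: missing column '{col}'")
    fractions = dict(zip(df["muscle"].astype(str), df["fraction"].astype(float)))
    groups = dict(zip(df["muscle"].astype(str), df["group"].astype(str)))
    return fractions, groups
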