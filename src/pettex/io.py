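"""Table and configuration plumbing: feature-table CSV round trips and the
YAML study configuration that seeds every pipeline stage."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from pettex.features import FeatureVector, feature_manifest
from pettex.matrices import MatrixConfig
from pettex.phantoms import PhantomSpec, coarse_texture_spec, fine_texture_spec
from pettex.stats import StatsConfig


def write_feature_table(vectors: list[tuple[str, str, FeatureVector]], path: str) -> None:
    """Write (subject_id, group, FeatureVector) rows as CSV in manifest order.

    The second line is a unit row (subject_id/group cells empty).
    """
    manifest = feature_manifest()
    names = [e["name"] for e in manifest]
    units = {e["name"]: e["unit"] for e in manifest}
    for sid, _, fv in vectors:
        if list(fv.values.keys()) != names:
            raise ValueError(f"subject {sid!r}: feature names do not match the manifest")
    rows = [{"subject_id": sid, "group": grp, **fv.values} for sid, grp, fv in vectors]
    df = pd.DataFrame(rows, columns=["subject_id", "group"] + names)
    unit_row = pd.DataFrame([{"subject_id": "", "group": "",
                              **{n: units[n] for n in names}}])
    out = pd.concat([unit_row, df], ignore_index=True)
    out.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, skiprows=[1])
    num_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    df[num_cols] = df[num_cols].astype(float)
    return df


# --------------------------------------------------------------------------
# study configuration


@dataclass
class SegmentationConfig:
    max_iter: int = 100
    tol: float = 1e-4


@dataclass
class ArmConfig:
    n: int = 7
    spec: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass
class StudyConfig:
    """Everything needed to rerun a study: design, stage params, one seed."""

    seed: int = 0
    treated: ArmConfig = field(default_factory=lambda: ArmConfig(spec=fine_texture_spec()))
    control: ArmConfig = field(default_factory=lambda: ArmConfig(spec=coarse_texture_spec()))
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    Ng: int = 64
    matrix: MatrixConfig = field(default_factory=MatrixConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix"]["directions"] = [list(v) for v in d["matrix"]["directions"]]
        for arm in ("treated", "control"):
            spec = d[arm]["spec"]
            if spec.get("grid_shape") is not None:
                spec["grid_shape"] = list(spec["grid_shape"])
        return d

    def dump(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_ALLOWED_TOP = {"seed", "treated", "control", "segmentation", "Ng", "matrix", "stats"}


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}")
    kwargs = {}
    for key, val in data.items():
        sub = {"spec": PhantomSpec, "segmentation": SegmentationConfig,
               "matrix": MatrixConfig, "stats": StatsConfig,
               "treated": ArmConfig, "control": ArmConfig}.get(key)
        if sub is not None and isinstance(val, dict):
            kwargs[key] = _build(sub, val, f"{path}.{key}" if path else key)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str) -> StudyConfig:
    """Load and validate a YAML study configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(data) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = _build(StudyConfig, data, "")
    if isinstance(cfg.matrix.directions, list):
        cfg.matrix.directions = tuple(tuple(d) for d in cfg.matrix.directions)
    for arm in (cfg.treated, cfg.control):
        if arm.spec.grid_shape is not None:
            arm.spec.grid_shape = tuple(arm.spec.grid_shape)
        arm.spec.validate()
    return cfg
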