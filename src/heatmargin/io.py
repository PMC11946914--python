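"""Schema-validated table readers/writers, run configuration, manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .simulate import (ECOTYPES, ENDPOINTS, LIFE_STAGES, MEDIA,
                       MICROHABITATS, SCENARIO_OFFSETS)

__all__ = ["RunConfig", "read_traits", "write_traits", "read_occurrences",
           "read_temps", "read_table", "write_table", "write_manifest",
           "validate_tables", "SchemaViolation"]

TRAIT_COLUMNS = ["species", "ctmax", "ctmax_se", "t_acc", "acc_duration",
                 "ramp_rate", "endpoint", "medium", "life_stage", "ecotype",
                 "body_mass"]
_VOCAB = {"endpoint": set(ENDPOINTS), "medium": set(MEDIA),
          "life_stage": set(LIFE_STAGES), "ecotype": set(ECOTYPES),
          "microhabitat": set(MICROHABITATS),
          "scenario": set(SCENARIO_OFFSETS)}


@dataclass
class SchemaViolation:
    table: str
    kind: str
    detail: str

    def __str__(self) -> str:
        return f"[{self.table}] {self.kind}: {self.detail}"


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run; round-trips through YAML."""

    out_dir: str = "heatmargin_run"
    traits: str | None = None
    tree: str | None = None
    occurrences: str | None = None
    temps: dict = field(default_factory=dict)  # (habitat, scenario) -> path
    scenarios: list = field(default_factory=lambda: list(SCENARIO_OFFSETS))
    microhabitats: list = field(default_factory=lambda: list(MICROHABITATS))
    variant: str = "default"
    sigma_cap: float = 1.0
    sigma_mode: str = "fixed_cap"
    window: int = 7
    n_cycles: int = 5
    mcmc_iterations: int = 4000
    mcmc_burn_in: int = 1000
    mcmc_thin: int = 3
    seed: int = 0
    simulate: dict | None = None   # SimConfig dict -> generate inputs first

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------
# readers / writers

def read_table(path: str | Path, required: list[str],
               name: str = "table") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} at {path} missing columns {missing}")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = read_table(path, TRAIT_COLUMNS, name="traits")
    return df[TRAIT_COLUMNS]


def write_traits(df: pd.DataFrame, path: str | Path) -> None:
    df[TRAIT_COLUMNS].to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    return read_table(path, ["species", "cell_id", "lat", "lon"],
                      name="occurrences")


def read_temps(path: str | Path) -> pd.DataFrame:
    return read_table(path, ["cell_id", "lat", "lon", "date", "year",
                             "daily_max", "microhabitat", "scenario"],
                      name="temps")


def write_table(df: pd.DataFrame, path: str | Path,
                manifest: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if manifest is not None:
        write_manifest(path, manifest, n_rows=len(df))


def write_manifest(table_path: str | Path, manifest: dict,
                   n_rows: int | None = None) -> None:
    path = Path(str(table_path) + ".manifest.json")
    payload = dict(manifest)
    if n_rows is not None:
        payload["n_rows"] = n_rows
    path.write_text(json.dumps(payload, indent=2, default=str))


# ---------------------------------------------------------------------
# validation

def _check_vocab(df: pd.DataFrame, table: str,
                 violations: list[SchemaViolation]) -> None:
    for col, vocab in _VOCAB.items():
        if col not in df.columns:
            continue
        bad = set(df[col].dropna().astype(str)) - vocab
        if bad:
            violations.append(SchemaViolation(
                table, "vocabulary", f"{col} has unknown values {sorted(bad)[:5]}"))


def validate_tables(traits: pd.DataFrame | None = None,
                    tree_tips: list[str] | None = None,
                    occurrences: pd.DataFrame | None = None,
                    temps: pd.DataFrame | None = None) -> list[SchemaViolation]:
    """Schema, vocabulary and referential-integrity checks across tables."""
    v: list[SchemaViolation] = []
    if traits is not None:
        _check_vocab(traits, "traits", v)
        has_ct = traits["ctmax"].notna()
        if (has_ct & traits["ctmax_se"].isna()).any():
            v.append(SchemaViolation("traits", "integrity",
                                     "observed ctmax without ctmax_se"))
        bad_se = traits["ctmax_se"].dropna() <= 0
        if bad_se.any():
            v.append(SchemaViolation("traits", "range",
                                     f"{int(bad_se.sum())} non-positive ctmax_se"))
        if tree_tips is not None:
            missing = set(traits["species"]) - set(tree_tips)
            if missing:
                v.append(SchemaViolation(
                    "traits", "reference",
                    f"species not in tree: {sorted(missing)[:5]}"))
    if occurrences is not None:
        dup = occurrences.duplicated(["species", "cell_id"])
        if dup.any():
            v.append(SchemaViolation("occurrences", "duplicate",
                                     f"{int(dup.sum())} duplicated species-cell rows"))
        if tree_tips is not None:
            missing = set(occurrences["species"]) - set(tree_tips)
            if missing:
                v.append(SchemaViolation(
                    "occurrences", "reference",
                    f"species not in tree: {sorted(missing)[:5]}"))
        if temps is not None:
            missing_cells = set(occurrences["cell_id"]) - set(temps["cell_id"])
            if missing_cells:
                v.append(SchemaViolation(
                    "occurrences", "reference",
                    f"cells without temperature data: {sorted(missing_cells)[:5]}"))
    if temps is not None:
        _check_vocab(temps, "temps", v)
        if temps["daily_max"].isna().any():
            v.append(SchemaViolation("temps", "integrity",
                                     "missing daily_max values"))
    return v
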