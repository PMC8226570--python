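"""Table/config I/O and validation shared by the pipeline stages.

The single interchange format between stages is a CSV with the canonical
columns ``id, net_charge, total_dipole, transversal_dipole, mpa_mean,
mpa_sd, alogp, accumulation`` (extra columns pass through untouched).
Configs are YAML/JSON with a ``pore`` and a ``coefficients`` block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .pipeline import DEFAULT_ACCUMULATION_CUTOFF, DEFAULT_ALOGP_CUTOFF
from .pore import PoreModel, ScoringCoefficients

__all__ = [
    "SchemaError",
    "RunConfig",
    "CANONICAL_COLUMNS",
    "read_compound_table",
    "write_compound_table",
    "write_report",
    "load_run_config",
    "example_config_path",
]

CANONICAL_COLUMNS = (
    "id",
    "net_charge",
    "total_dipole",
    "transversal_dipole",
    "mpa_mean",
    "mpa_sd",
    "alogp",
    "accumulation",
)

_NUMERIC_COLUMNS = CANONICAL_COLUMNS[1:]

#: Fixed output precision: 12 significant digits survive a CSV round-trip.
FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """Input table violates the canonical schema; carries per-row messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Resolved run configuration: pore, coefficients, cutoffs, settings."""

    pore: PoreModel
    coefficients: ScoringCoefficients | None
    accumulation_cutoff: float = DEFAULT_ACCUMULATION_CUTOFF
    alogp_cutoff: float = DEFAULT_ALOGP_CUTOFF
    n_directions: int = 256
    grid_resolution: float = 0.1
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.accumulation_cutoff <= 0 or self.alogp_cutoff <= 0:
            raise ValueError("filter cutoffs must be positive")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")


def read_compound_table(
    path: str | Path, require_accumulation: bool = True
) -> pd.DataFrame:
    """Read and validate a canonical compound CSV.

    Checks the required columns, numeric parsability, non-negative
    accumulation and id uniqueness; all violations are collected into one
    :class:`SchemaError` with 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    required = set(CANONICAL_COLUMNS)
    if not require_accumulation:
        required.discard("accumulation")
    errors: list[str] = []
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError([f"missing required columns: {sorted(missing)}"])
    if frame.empty:
        raise SchemaError(["table has no data rows"])
    for col in _NUMERIC_COLUMNS:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        for idx in bad:
            errors.append(
                f"row {idx + 1}: non-numeric value {frame.at[idx, col]!r} "
                f"in column {col!r}"
            )
        frame[col] = coerced
    if "accumulation" in frame.columns:
        neg = frame.index[frame["accumulation"] < 0]
        for idx in neg:
            errors.append(
                f"row {idx + 1}: negative accumulation "
                f"{frame.at[idx, 'accumulation']}"
            )
    frame["id"] = frame["id"].astype(str)
    duplicated = frame["id"][frame["id"].duplicated()].unique()
    for dup in duplicated:
        errors.append(f"duplicate compound id {dup!r}")
    if errors:
        raise SchemaError(errors)
    return frame


def write_compound_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a compound table with stable column order and fixed precision."""
    ordered = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    ordered += [c for c in frame.columns if c not in ordered]
    frame.loc[:, ordered].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(
    per_compound: pd.DataFrame,
    report: dict,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write compounds.csv, report.json and run_metadata.json to ``out_dir``.

    Reruns with identical inputs produce byte-identical compounds.csv and
    report.json; the metadata file records the config hash and seed for
    provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out_dir / "compounds.csv",
        "report": out_dir / "report.json",
        "metadata": out_dir / "run_metadata.json",
    }
    write_compound_table(per_compound, paths["compounds"])
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True))
    import porinperm

    metadata = {
        "package_version": porinperm.__version__,
        "config_hash": _config_hash(config.raw) if config else None,
        "seed": config.seed if config else None,
        "n_rows": int(len(per_compound)),
    }
    paths["metadata"].write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return paths


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration.

    Schema::

        pore:
          name: OmpF
          v_pore_mV: -30.0
          e_pore_mV_per_A: 6.0
          area_mean_A2: 50.0
          area_sd_A2: 9.0
        coefficients: {alpha: ..., beta: ..., gamma: ..., delta: ...}
        filters: {accumulation_cutoff: 45.0, alogp_cutoff: 2.9}
        descriptors: {n_directions: 256, grid_resolution: 0.1, seed: 0}

    ``coefficients`` may be omitted, leaving a config that only supports
    descriptor computation and coefficient fitting.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "pore" not in raw:
        raise SchemaError(["config must be a mapping with a 'pore' block"])
    p = raw["pore"]
    try:
        pore = PoreModel(
            name=str(p.get("name", "pore")),
            v_pore=float(p["v_pore_mV"]),
            e_pore=float(p["e_pore_mV_per_A"]),
            pore_area_mean=float(p["area_mean_A2"]),
            pore_area_sd=float(p["area_sd_A2"]),
        )
    except KeyError as exc:
        raise SchemaError([f"pore block missing key {exc.args[0]!r}"]) from exc
    coefficients = None
    if raw.get("coefficients"):
        c = raw["coefficients"]
        try:
            coefficients = ScoringCoefficients(
                alpha=float(c["alpha"]),
                beta=float(c["beta"]),
                gamma=float(c["gamma"]),
                delta=float(c["delta"]),
            )
        except KeyError as exc:
            raise SchemaError(
                [f"coefficients block missing key {exc.args[0]!r}"]
            ) from exc
    filters = raw.get("filters", {})
    desc = raw.get("descriptors", {})
    return RunConfig(
        pore=pore,
        coefficients=coefficients,
        accumulation_cutoff=float(
            filters.get("accumulation_cutoff", DEFAULT_ACCUMULATION_CUTOFF)
        ),
        alogp_cutoff=float(filters.get("alogp_cutoff", DEFAULT_ALOGP_CUTOFF)),
        n_directions=int(desc.get("n_directions", 256)),
        grid_resolution=float(desc.get("grid_resolution", 0.1)),
        seed=int(desc.get("seed", 0)),
        raw=raw,
    )


def example_config_path() -> Path:
    """Path of the bundled illustrative OmpF configuration."""
    return Path(__file__).parent / "data" / "ompf_example.yaml"
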