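"""Configuration and file I/O: YAML configs, twin tables, genotype tables.

Bundled fixtures transcribe the published input tables exactly as printed
(rounded); all full-precision recomputation happens downstream, which is why
a handful of one-ulp reproduction discrepancies are tracked explicitly
rather than patched in the fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .concordance import EpidemiologicalObservables, TwinPairCounts
from .partition import GenotypeFrequencyTable

__all__ = [
    "AnalysisConfig",
    "load_config",
    "default_config",
    "load_observables",
    "read_twin_tables",
    "read_genotype_tables",
    "read_region_registry",
    "read_disease_registry",
    "printed_values",
]


def _data_path(name: str):
    return resources.files("twinrisk.data").joinpath(name)


@dataclass(frozen=True)
class StudyCalibration:
    """Whole-study ascertainment calibration inputs."""

    concordant: int
    discordant: int
    overall_probandwise: float
    b_target: float


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the full-analysis driver needs, schema-validated on load."""

    observables: EpidemiologicalObservables
    study: StudyCalibration
    twin_tables: pd.DataFrame
    gender_partition: dict[str, float]
    carrier_partition: dict[str, float]
    environment: dict[str, float]
    regions: pd.DataFrame
    diseases: pd.DataFrame
    genotype_tables: dict[tuple[str, str], GenotypeFrequencyTable]
    carrier_tables: pd.DataFrame
    raw: dict[str, Any] = field(default_factory=dict)


def _build_observables(block: dict[str, Any]) -> EpidemiologicalObservables:
    known = {
        "prevalence",
        "mz_raw",
        "dz_raw",
        "sib_raw",
        "female_fraction_cases",
        "carrier_fraction_cases",
        "carrier_fraction_population",
        "per_gender",
    }
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown observables fields: {sorted(unknown)}")
    return EpidemiologicalObservables(**block)


def load_observables(path: str | Path | None = None) -> EpidemiologicalObservables:
    """Observables block from a YAML config (bundled MS fixture by default)."""
    doc = _load_yaml(path)
    return _build_observables(doc["observables"])


def _load_yaml(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        text = _data_path("ms_observables.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    return doc


def read_twin_tables(path: str | Path | None = None) -> pd.DataFrame:
    """Twin tables with columns zygosity, subgroup, concordant, discordant."""
    src = _data_path("twin_tables.csv") if path is None else Path(path)
    df = pd.read_csv(src)
    required = {"zygosity", "subgroup", "concordant", "discordant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"twin table missing columns: {sorted(missing)}")
    return df


def twin_counts(df: pd.DataFrame, zygosity: str, subgroup: str) -> TwinPairCounts:
    row = df[(df.zygosity == zygosity) & (df.subgroup == subgroup)]
    if len(row) != 1:
        raise ValueError(f"expected one row for ({zygosity}, {subgroup}), got {len(row)}")
    rec = row.iloc[0]
    return TwinPairCounts(
        int(rec.concordant), int(rec.discordant), zygosity=zygosity, subgroup=subgroup
    )


def read_genotype_tables(
    path: str | Path | None = None,
) -> dict[tuple[str, str], GenotypeFrequencyTable]:
    """Genotype-dose frequency tables keyed by (cohort, group).

    Printed frequencies are rounded and may not sum to exactly 1; triples are
    renormalized on ingest.
    """
    src = _data_path("genotype_tables.csv") if path is None else Path(path)
    df = pd.read_csv(src)
    out: dict[tuple[str, str], GenotypeFrequencyTable] = {}
    for rec in df.to_dict("records"):
        triple = (
            float(rec["freq_2copy"]),
            float(rec["freq_1copy"]),
            float(rec["freq_0copy"]),
        )
        total = sum(triple)
        if total <= 0:
            raise ValueError(f"degenerate genotype row: {rec}")
        out[(str(rec["cohort"]), str(rec["group"]))] = GenotypeFrequencyTable(
            freq_2copy=triple[0] / total,
            freq_1copy=triple[1] / total,
            freq_0copy=triple[2] / total,
            source_label=f"{rec['cohort']}:{rec['group']}",
        )
    return out


def read_region_registry(path: str | Path | None = None) -> pd.DataFrame:
    """Regional registry normalized to the susceptibility-module schema."""
    src = _data_path("regions.csv") if path is None else Path(path)
    df = pd.read_csv(src)
    required = {
        "region",
        "prevalence_low_per1e5",
        "prevalence_high_per1e5",
        "probandwise_mz_percent",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region registry missing columns: {sorted(missing)}")
    return pd.DataFrame(
        {
            "region": df["region"],
            "prevalence_low": df["prevalence_low_per1e5"],
            "prevalence_high": df["prevalence_high_per1e5"],
            "probandwise_mz": df["probandwise_mz_percent"] / 100.0,
        }
    )


def read_disease_registry(path: str | Path | None = None) -> pd.DataFrame:
    src = _data_path("diseases.csv") if path is None else Path(path)
    df = pd.read_csv(src)
    return pd.DataFrame(
        {
            "region": df["disease"],
            "prevalence_low": df["prevalence_low_percent"] / 100.0,
            "prevalence_high": df["prevalence_high_percent"] / 100.0,
            "probandwise_mz": df["probandwise_mz_percent"] / 100.0,
        }
    )


def printed_values() -> dict[str, Any]:
    """Published table cells (and the known one-ulp discrepancies) for regression."""
    return yaml.safe_load(_data_path("printed_values.yaml").read_text())


def default_config() -> AnalysisConfig:
    """Bundled MS configuration (all fixture tables)."""
    return load_config(None)


def load_config(path: str | Path | None) -> AnalysisConfig:
    doc = _load_yaml(path)
    base = Path(path).parent if path is not None else None

    def _resolve(key: str, default_loader, loader):
        entry = doc.get("paths", {}).get(key)
        if entry is None:
            return default_loader()
        p = Path(entry)
        if base is not None and not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"configured path for {key!r} does not exist: {p}")
        return loader(p)

    study_block = doc.get("study", {})
    study = StudyCalibration(
        concordant=int(study_block.get("concordant", 24)),
        discordant=int(study_block.get("discordant", 109)),
        overall_probandwise=float(study_block.get("overall_probandwise", 0.253)),
        b_target=float(study_block.get("b_target", 0.134)),
    )
    carrier_src = _data_path("carrier_tables.csv")
    return AnalysisConfig(
        observables=_build_observables(doc["observables"]),
        study=study,
        twin_tables=_resolve("twin_tables", read_twin_tables, read_twin_tables),
        gender_partition=doc.get("gender_partition", {"A": 0.68, "A0": 0.50}),
        carrier_partition=doc.get("carrier_partition", {"A": 0.55, "A0": 0.24}),
        environment=doc.get("environment", {}),
        regions=_resolve("regions", read_region_registry, read_region_registry),
        diseases=_resolve("diseases", read_disease_registry, read_disease_registry),
        genotype_tables=_resolve(
            "genotype_tables", read_genotype_tables, read_genotype_tables
        ),
        carrier_tables=pd.read_csv(carrier_src),
        raw=doc,
    )
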