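"""File ingestion, validation, run configuration and manifests.

All tabular inputs are plain text (TSV/CSV); parsers reject malformed
records instead of coercing them, with one documented exception: GFP
percentages are converted to fractions on ingestion (logged).
"""

from __future__ import annotations

import configparser
import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .screen import GuideCountMatrix
from .signature import DEFAULT_ROSTER, ReferenceSet, Signature

log = logging.getLogger("moakit")

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_count_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a guide count TSV (sgRNA, gene, then one column per sample).

    Returns ``(counts, guides)``; duplicate guide ids, negative or
    non-integer counts are schema errors reported with their line number.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sgRNA", "gene"]:
        raise SchemaError(f"{path}: header must start with 'sgRNA\\tgene'")
    sample_cols = list(df.columns[2:])
    if not sample_cols:
        raise SchemaError(f"{path}: no sample columns")
    dup = df["sgRNA"].duplicated()
    if dup.any():
        line = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise SchemaError(f"{path}:{line}: duplicate guide id {df['sgRNA'][dup].iloc[0]!r}")
    values = df[sample_cols].to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) < 0) | (
        values.astype(float) != np.floor(values.astype(float))
    )
    if bad.any():
        line = int(np.nonzero(bad.any(axis=1))[0][0]) + 2
        raise SchemaError(f"{path}:{line}: counts must be non-negative integers")
    counts = df.set_index("sgRNA")[sample_cols].astype(np.int64)
    guides = df.set_index("sgRNA")[["gene"]].copy()
    guides["nontargeting"] = guides["gene"] == "NONTARGETING"
    return counts, guides


def write_count_table(path, counts: pd.DataFrame, guides: pd.DataFrame) -> None:
    out = pd.DataFrame({"sgRNA": counts.index, "gene": guides["gene"].to_numpy()})
    for col in counts.columns:
        out[col] = counts[col].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "role", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    df["treatment"] = df["treatment"].fillna("")
    return df.set_index("sample")


def write_sample_sheet(path, samples: pd.DataFrame) -> None:
    samples.reset_index().to_csv(path, index=False)


def load_screen(counts_path, samples_path) -> GuideCountMatrix:
    counts, guides = read_count_table(counts_path)
    samples = read_sample_sheet(samples_path)
    return GuideCountMatrix(counts=counts, guides=guides, samples=samples)


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------

_SYNERGY_COLS = {"plate", "well", "drug", "dose_a", "dose_b", "replicate", "signal", "role"}
_FLICK_COLS = {"plate", "well", "condition", "drug", "dose", "time_h", "sytox_signal"}
_LYSIS_COLS = {"plate", "well", "kind", "signal"}


def _read_checked(path, required: set, label: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required {label} columns {sorted(missing)}")
    unknown = set(df.columns) - required
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(unknown)}", stacklevel=2)
    return df


def read_synergy_csv(path) -> pd.DataFrame:
    """Long-format dose-response plate CSV."""
    return _read_checked(path, _SYNERGY_COLS, "synergy plate")


def read_flick_csv(path) -> pd.DataFrame:
    """Long-format death-kinetics plate CSV."""
    return _read_checked(path, _FLICK_COLS, "FLICK plate")


def read_lysis_csv(path) -> pd.DataFrame:
    df = _read_checked(path, _LYSIS_COLS, "lysis table")
    bad = ~df["kind"].isin(["t0_lysis", "end_lysis"])
    if bad.any():
        raise SchemaError(f"{path}: lysis kind must be t0_lysis or end_lysis")
    return df


def read_signature_csv(path) -> pd.DataFrame:
    """Competition assay CSV (drug, hairpin, gfp_treated, gfp_control, replicate).

    GFP columns given as percentages (values > 1.5) are converted to
    fractions, with a log entry.
    """
    df = _read_checked(
        path, {"drug", "hairpin", "gfp_treated", "gfp_control", "replicate"}, "signature assay"
    )
    for col in ("gfp_treated", "gfp_control"):
        vals = df[col].astype(float)
        if (vals > 1.5).any():
            log.info("converting %s from percent to fraction", col)
            vals = vals / 100.0
        if ((vals < 0) | (vals > 1)).any():
            raise SchemaError(f"{path}: {col} outside [0, 1] after conversion")
        df[col] = vals
    return df


def read_reference_tsv(path, roster: tuple = DEFAULT_ROSTER) -> ReferenceSet:
    """Reference signature TSV: drug, class, then one RI column per hairpin."""
    df = pd.read_csv(path, sep="\t")
    missing = ({"drug", "class"} | set(roster)) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing reference columns {sorted(missing)}")
    signatures = [
        Signature(drug=row["drug"], ri=np.array([row[h] for h in roster]), roster=roster)
        for _, row in df.iterrows()
    ]
    return ReferenceSet(signatures=signatures, labels=df["class"].tolist())


def write_reference_tsv(path, ref: ReferenceSet) -> None:
    roster = ref.signatures[0].roster
    rows = []
    for sig, label in zip(ref.signatures, ref.labels):
        row = {"drug": sig.drug, "class": label}
        row.update({h: v for h, v in zip(roster, sig.ri)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration and manifests
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with its documented default."""

    seed: int = 0
    fa_clip_eps: float = 1e-4
    pseudocount: float = 0.5
    bootstrap_b: int = 1000
    permutation_b: int = 999
    k: int = 3
    fdr_threshold: float = 0.1
    lr_threshold: float = 1.0
    p_threshold: float = 0.05

    def __post_init__(self):
        if not 0 < self.fa_clip_eps < 0.5:
            raise SchemaError("fa_clip_eps must be in (0, 0.5)")
        if self.bootstrap_b < 1 or self.permutation_b < 1:
            raise SchemaError("bootstrap/permutation B must be >= 1")
        if not 0 < self.fdr_threshold < 1 or not 0 < self.p_threshold < 1:
            raise SchemaError("thresholds must be fractions in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Plain-text config: ``[stage]`` sections of ``key = value`` lines."""
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise SchemaError(f"config file {path} not found or empty")
        kwargs = {}
        casts = {f.name: type(f.default) for f in cls.__dataclass_fields__.values()}
        for section in parser.sections():
            for key, value in parser.items(section):
                if key not in casts:
                    warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
                    continue
                kwargs[key] = casts[key](value)
        return cls(**kwargs)


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every output set."""

    tool_version: str
    config: dict
    input_checksums: dict
    seed: int
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def build_manifest(config: RunConfig, inputs: list) -> RunManifest:
    return RunManifest(
        tool_version=__version__,
        config=asdict(config),
        input_checksums={str(p): _checksum(p) for p in inputs},
        seed=config.seed,
    )
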