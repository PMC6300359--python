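"""Tabular I/O with validation.

All tables are UTF-8 tab-separated with one mandatory header row;
'#'-prefixed lines are comments.  Readers validate column presence,
numeric types and value constraints, and name the offending row/column in
errors.  Writers emit a deterministic column order so a full pipeline run
is byte-for-byte reproducible.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError
from .exon_usage import REGIONS, ExonRecord, SampleCounts
from .mechanics import PASSIVE_STATES, PassiveCurve

# schema name -> {column: (dtype kind, constraint)} where constraint is
# one of None, "nonneg", "positive"
SCHEMAS: dict[str, dict[str, tuple[str, str | None]]] = {
    "counts": {
        "exon_index": ("int", None),
        "inclusion_reads": ("int", "nonneg"),
        "exclusion_reads": ("int", "nonneg"),
    },
    "annotation": {
        "exon_index": ("int", None),
        "region": ("str", None),
        "length_nt": ("int", "positive"),
        "n_residues": ("int", "nonneg"),
        "deleted_in_model": ("bool", None),
    },
    "epitope": {
        "sarcomere_length_um": ("float", "positive"),
        "separation_nm": ("float", "nonneg"),
    },
    "profile": {
        "position_nm": ("float", None),
        "intensity": ("float", "nonneg"),
    },
    "passive": {
        "state": ("str", None),
        "sarcomere_length_um": ("float", "positive"),
        "tension_mn_mm2": ("float", "nonneg"),
    },
    "ff": {
        "frequency_hz": ("float", "positive"),
        "tension_mn_mm2": ("float", None),
    },
}

_CASTERS = {
    "int": lambda s: s.astype(int),
    "float": lambda s: s.astype(float),
    "str": lambda s: s.astype(str),
    "bool": lambda s: s.map(
        {"True": True, "False": False, "1": True, "0": False, True: True, False: False}
    ),
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a tab-separated table against a named schema."""
    if schema not in SCHEMAS:
        raise TableFormatError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: no data rows") from None
    if raw.empty:
        raise TableFormatError(f"{path}: no data rows")
    missing = set(spec) - set(raw.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame(index=raw.index)
    for col, (kind, constraint) in spec.items():
        try:
            out[col] = _CASTERS[kind](raw[col])
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise TableFormatError(
                f"{path}: non-{kind} value in column {col!r} at line {row}"
            ) from None
        if kind == "bool" and out[col].isna().any():
            row = int(out.index[out[col].isna()][0]) + 2
            raise TableFormatError(
                f"{path}: non-boolean value in column {col!r} at line {row}"
            )
        if constraint in ("nonneg", "positive"):
            limit = 0 if constraint == "nonneg" else np.finfo(float).tiny
            bad = out.index[out[col] < limit]
            if len(bad):
                raise TableFormatError(
                    f"{path}: column {col!r} must be "
                    f"{'non-negative' if constraint == 'nonneg' else 'positive'} "
                    f"(line {int(bad[0]) + 2})"
                )
    if "exon_index" in out.columns and out["exon_index"].duplicated().any():
        dup = sorted(set(out.loc[out["exon_index"].duplicated(), "exon_index"]))
        raise TableFormatError(f"{path}: duplicate exon_index {dup}")
    if "region" in out.columns:
        bad = out.index[~out["region"].isin(REGIONS)]
        if len(bad):
            raise TableFormatError(
                f"{path}: unknown region {out.loc[bad[0], 'region']!r} "
                f"at line {int(bad[0]) + 2}"
            )
    if "state" in out.columns:
        bad = out.index[~out["state"].isin(PASSIVE_STATES)]
        if len(bad):
            raise TableFormatError(
                f"{path}: unknown state {out.loc[bad[0], 'state']!r} "
                f"at line {int(bad[0]) + 2}"
            )
    return out


def write_results(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with deterministic column order.

    Floats are written with 12 significant digits so a read/write
    round-trip preserves values to ~1e-12 relative tolerance.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    frame.to_csv(buf, sep="\t", index=False, float_format="%.12g", lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_annotation(path: str | Path) -> list[ExonRecord]:
    """Read an exon annotation table into ExonRecord objects."""
    table = read_table(path, "annotation")
    return [
        ExonRecord(
            exon_index=int(r.exon_index),
            region=r.region,
            length_nt=int(r.length_nt),
            n_residues=int(r.n_residues),
            deleted_in_model=bool(r.deleted_in_model),
        )
        for r in table.itertuples()
    ]


def write_annotation(annotation: list[ExonRecord], path: str | Path) -> Path:
    frame = pd.DataFrame(
        {
            "exon_index": [e.exon_index for e in annotation],
            "region": [e.region for e in annotation],
            "length_nt": [e.length_nt for e in annotation],
            "n_residues": [e.n_residues for e in annotation],
            "deleted_in_model": [e.deleted_in_model for e in annotation],
        }
    )
    return write_results(frame, path)


def read_sample_counts(
    path: str | Path,
    sample_id: str | None = None,
    genotype: str = "WT",
    muscle: str = "unknown",
    read_length: int = 100,
) -> SampleCounts:
    """Read one per-sample exon counts table."""
    counts = read_table(path, "counts")
    return SampleCounts(
        sample_id=sample_id or Path(path).stem,
        genotype=genotype,
        muscle=muscle,
        read_length=read_length,
        counts=counts,
    )


def read_passive_curves(path: str | Path) -> dict[str, PassiveCurve]:
    """Read a passive-tension table (with state column) into curves."""
    table = read_table(path, "passive")
    curves = {}
    for state, group in table.groupby("state", sort=False):
        group = group.sort_values("sarcomere_length_um")
        curves[state] = PassiveCurve(
            state=state,
            sarcomere_length_um=group["sarcomere_length_um"].to_numpy(),
            tension_mn_mm2=group["tension_mn_mm2"].to_numpy(),
        )
    return curves


def write_passive_curves(curves: dict[str, PassiveCurve], path: str | Path) -> Path:
    frames = [
        pd.DataFrame(
            {
                "state": c.state,
                "sarcomere_length_um": c.sarcomere_length_um,
                "tension_mn_mm2": c.tension_mn_mm2,
            }
        )
        for c in curves.values()
    ]
    return write_results(pd.concat(frames, ignore_index=True), path)
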