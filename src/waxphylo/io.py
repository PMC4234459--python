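"""Reading and writing the pipeline's tabular formats.

Trait tables are CSV/TSV with one row per species and columns
``species, lineage, growth_form, pathway, dD_<compound> x7, dD_xylem,
dD_leafwater, dD_environ``; empty cells are missing values.  Regime specs
are TSV lines ``regime_id<TAB>tip1,tip2`` naming two tips whose MRCA
spans the painted clade.  Numeric outputs are TSV with ``#``-prefixed
header comments recording provenance (source kind, seed, normalizer).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import CANONICAL_COMPOUNDS
from .fractionation import FractionationMatrix, SpeciesSample

_LABEL_COLS = ("lineage", "growth_form", "pathway")


def read_samples(path: str | Path) -> list[SpeciesSample]:
    """Read a trait table (CSV or TSV by extension) into samples."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if "species" not in df.columns or "dD_environ" not in df.columns:
        raise ValueError(f"{path}: need at least 'species' and 'dD_environ' columns")
    samples = []
    for _, row in df.iterrows():
        dD_wax = {}
        for c in CANONICAL_COMPOUNDS:
            col = f"dD_{c.id}"
            if col in df.columns and np.isfinite(row[col]):
                dD_wax[c.id] = float(row[col])
        def _opt(col: str) -> float | None:
            if col in df.columns and pd.notna(row[col]) and np.isfinite(row[col]):
                return float(row[col])
            return None
        labels = {k: (str(row[k]) if k in df.columns and pd.notna(row[k]) else None)
                  for k in _LABEL_COLS}
        samples.append(SpeciesSample(
            species=str(row["species"]), dD_wax=dD_wax,
            dD_environ=float(row["dD_environ"]),
            dD_xylem=_opt("dD_xylem"), dD_leafwater=_opt("dD_leafwater"),
            **labels,
        ))
    return samples


def write_samples(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_matrix(
    matrix: FractionationMatrix, path: str | Path, header: dict | None = None
) -> None:
    """Fractionation matrix as TSV with a source_kind header comment."""
    meta = {"source_kind": matrix.source_kind,
            "fallback_species": ",".join(matrix.fallback_species) or "none"}
    meta.update(header or {})
    _write_commented(matrix.values, path, meta, index_label="species")


def write_frame(df: pd.DataFrame, path: str | Path,
                header: dict | None = None, index_label: str | None = None) -> None:
    _write_commented(df, path, header or {}, index_label=index_label)


def _write_commented(df: pd.DataFrame, path: str | Path, meta: dict,
                     index_label: str | None) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, float_format="%.9g")


def read_regime_specs(path: str | Path) -> list[tuple[int, list[str]]]:
    """Parse ``regime_id<TAB>tip1,tip2`` lines into clade specs."""
    specs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rid, tips = line.split("\t")
            specs.append((int(rid), [t.strip() for t in tips.split(",")]))
        except ValueError as exc:
            raise ValueError(f"bad regime spec line {line!r}") from exc
    return specs


def write_regime_specs(specs: list[tuple[int, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, tips in specs:
            fh.write(f"{rid}\t{','.join(tips)}\n")


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
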