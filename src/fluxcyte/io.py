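"""Readers and writers for the delimited text formats used by the pipeline.

Expression matrices are TSV/CSV with gene symbols in the first column and a
header row of sample ids; flux matrices are TSV with sample ids in the first
column and module ids in the header.  Marker sets come as YAML mappings
(``set_name: [genes]``) or two-column TSV (set_name, gene).  Output files
carry a header comment with the package version and seed.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .immunoscore import MarkerSet

__all__ = [
    "read_expression",
    "write_expression",
    "read_flux",
    "write_flux",
    "read_marker_sets",
    "write_table",
    "file_digest",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample matrix; rejects negative or non-finite values."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any() or not pd.notna(vals).all():
        raise ValueError(f"{path}: expression must be non-negative and finite")
    return df.astype(float)


def _header_comment(seed: int | None) -> str:
    seed_part = f" seed={seed}" if seed is not None else ""
    return f"# fluxcyte v{__version__}{seed_part}\n"


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                index_label: str | None = None) -> None:
    """Write a TSV with a version/seed comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index_label=index_label)


def write_expression(expr: pd.DataFrame, path: str | Path,
                     seed: int | None = None) -> None:
    write_table(expr, path, seed=seed, index_label="gene")


def write_flux(flux: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    write_table(flux, path, seed=seed, index_label="sample")


def read_flux(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_marker_sets(path: str | Path) -> dict[str, MarkerSet]:
    """Marker sets from YAML (name -> gene list) or TSV (set_name, gene)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of set name to gene list")
        return {name: MarkerSet(name, tuple(genes)) for name, genes in raw.items()}
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"set_name", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns set_name, gene")
    out = {}
    for name, grp in df.groupby("set_name", sort=False):
        out[str(name)] = MarkerSet(str(name), tuple(grp["gene"].astype(str)))
    return out


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
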