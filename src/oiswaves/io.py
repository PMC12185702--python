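"""Readers and writers for the plain-text formats used throughout the package.

Matrices are TSV with a header row of sample identifiers and a first column
of feature identifiers (features in rows, samples in columns).  Gene sets use
the GMT convention: one set per line, ``name<TAB>description<TAB>member...``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd


def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a feature x sample matrix.

    Raises
    ------
    ValueError
        If feature identifiers are duplicated (all offenders listed) or a
        row has the wrong number of fields (line number reported).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        n_fields = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if len(line.rstrip("\n").split(sep)) != n_fields:
                raise ValueError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate feature ids: {dup}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="feature")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping ``name -> member list``.

    Blank members are dropped; duplicated members within a set are
    de-duplicated (order preserved) with a warning; lines with no members
    are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            members = [m for m in fields[2:] if m.strip()]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"GMT set {name!r}: duplicated members de-duplicated")
            if not deduped:
                warnings.warn(f"GMT set {name!r} at line {lineno} is empty; skipped")
                continue
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            sets[name] = deduped
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
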