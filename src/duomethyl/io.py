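"""Tabular I/O: beta matrices, sample sheets, annotations, masks, GMT sets.

Everything is plain TSV (gzip transparently supported by pandas) so runs are
diffable and portable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"


def read_matrix(path) -> pd.DataFrame:
    """Read a sites x samples beta matrix (first column = site ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "site_id"
    if df.index.duplicated().any():
        raise ValueError(f"duplicate site IDs in {path}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample IDs in {path}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="site_id")


def read_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "mother_id": str, "newborn_id": str})
    required = {"pair_id", "mother_id", "newborn_id", "sex"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    if pairs["sex"].isna().any():
        raise ValueError("pair table has missing newborn sex")
    return pairs


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chromosome": str, "genes": str})
    if "site_id" not in ann.columns:
        raise ValueError("annotation must have a site_id column")
    ann["genes"] = ann["genes"].fillna("")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_mask(path) -> set[str]:
    """Read a probe mask file: one site ID per line, blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_gmt(path) -> dict[str, tuple[str, frozenset]]:
    """Read gene sets in GMT format: name <tab> description <tab> gene...

    Returns {name: (description, genes)}.
    """
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description and >= 1 gene")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene set {name!r}")
            sets[name] = (desc, frozenset(genes))
    return sets


def write_gmt(sets: dict[str, tuple[str, frozenset]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
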