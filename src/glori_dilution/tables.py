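"""Readers and writers for the pipeline's tabular interchange formats.

All tables are plain TSV with headers.  Per-sample GLORI count tables carry
the columns ``contig, pos0, strand, a_count, g_count`` where ``pos0`` is the
0-based genomic coordinate of the adenosine and ``a_count``/``g_count`` count
reads with the unconverted A and the deaminated G, respectively.

Writers use a fixed float format so that identical in-memory frames always
serialize byte-identically (pipeline determinism is checked at file level).
"""

from __future__ import annotations

import json
from typing import Any, Dict

import pandas as pd

from .errors import InputError

COUNTS_COLUMNS = ["contig", "pos0", "strand", "a_count", "g_count"]
FLOAT_FORMAT = "%.6g"


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "contig": str,
            "pos0": "int64",
            "strand": str,
            "a_count": "int64",
            "g_count": "int64",
        },
    )
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"counts table {path} missing columns {missing}")
    return df[COUNTS_COLUMNS]


def write_counts(df: pd.DataFrame, path: str) -> None:
    df[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_sites_bed(sites: pd.DataFrame, path: str) -> None:
    """BED6 with score = round(1000 * methylation level)."""
    bed = pd.DataFrame(
        {
            "contig": sites["contig"],
            "start": sites["pos0"],
            "end": sites["pos0"] + 1,
            "name": [
                f"{c}:{p}:{s}"
                for c, p, s in zip(
                    sites["contig"], sites["pos0"], sites["strand"]
                )
            ],
            "score": (1000 * sites["level"]).round().astype(int),
            "strand": sites["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(sites: pd.DataFrame, path: str) -> None:
    """bedGraph of methylation levels (strand collapsed, as conventional)."""
    bg = pd.DataFrame(
        {
            "contig": sites["contig"],
            "start": sites["pos0"],
            "end": sites["pos0"] + 1,
            "level": sites["level"],
        }
    ).sort_values(["contig", "start"], kind="mergesort")
    bg.to_csv(path, sep="\t", header=False, index=False, float_format=FLOAT_FORMAT)


def write_json(obj: Dict[str, Any], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str) -> Dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
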