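"""Tab-separated table I/O used by every stage.

All on-disk tables are UTF-8 TSV with a header row; missing values are
written as empty fields. Floats are written with %.10g so identical inputs
produce byte-identical files (the pipeline manifest digests rely on this).
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import pandas as pd

SEP = "\t"
FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep=SEP, index=index, na_rep="", float_format=FLOAT_FORMAT)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, index_col=index_col)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def file_digest(path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
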