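"""Readers and writers: JSONL corpora, CSV tables, theme configs, manifests.

The JSONL schema is one record per line with a canonical field order
(id, created_at as ISO-8601 UTC, text, duplicate_of, true_*, pred_*); absent
optional fields are written as null so write -> read -> write is byte-stable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import yaml

from .config import ThemeSpec

FIELD_ORDER = [
    "id", "created_at", "text", "duplicate_of",
    "true_sentiment", "true_organism", "true_relevance",
    "pred_relevance", "pred_sentiment", "pred_organism",
]
REQUIRED_FIELDS = ["id", "created_at", "text"]


class CorpusFormatError(ValueError):
    pass


def _iso(ts: pd.Timestamp) -> str:
    return ts.tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%SZ")


def write_corpus(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write records as JSONL in canonical field order."""
    path = Path(path)
    cols = [c for c in FIELD_ORDER if c in records.columns]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records[cols].itertuples(index=False):
            row = dict(zip(cols, rec))
            row["created_at"] = _iso(row["created_at"])
            for k, v in row.items():
                if pd.isna(v):
                    row[k] = None
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_corpus(path: Union[str, Path]) -> pd.DataFrame:
    """Read a JSONL corpus; malformed lines raise with their line number."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: invalid JSON ({exc})")
            missing = [f for f in REQUIRED_FIELDS if row.get(f) in (None, "")]
            if missing:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: missing required field(s) {missing}"
                )
            try:
                row["created_at"] = pd.Timestamp(row["created_at"])
                if row["created_at"].tzinfo is None:
                    row["created_at"] = row["created_at"].tz_localize("UTC")
                else:
                    row["created_at"] = row["created_at"].tz_convert("UTC")
            except ValueError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: bad timestamp ({exc})")
            rows.append(row)
    cols = [c for c in FIELD_ORDER if any(c in r for r in rows)] if rows else REQUIRED_FIELDS
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df["created_at"] = pd.to_datetime(df["created_at"], utc=True)
    return df


def write_annotations(annotations: pd.DataFrame, path: Union[str, Path]) -> None:
    annotations.to_csv(path, index=False, lineterminator="\n")


def read_annotations(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tweet_id": str, "annotator_id": str})


def load_themes(path: Union[str, Path]) -> list[ThemeSpec]:
    """Theme table from YAML (name: pattern) or CSV (name,pattern)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        return [ThemeSpec(name=k, pattern=v) for k, v in raw.items()]
    df = pd.read_csv(path)
    return [ThemeSpec(name=r["name"], pattern=r["pattern"]) for _, r in df.iterrows()]


def sha256_of(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(path: Union[str, Path], rows: pd.DataFrame,
                float_format: str = "%.10g") -> dict:
    """Write a CSV table and return its manifest entry (path, rows, sha256)."""
    path = Path(path)
    rows.to_csv(path, index=False, lineterminator="\n", float_format=float_format)
    return {"path": path.name, "rows": int(len(rows)), "sha256": sha256_of(path)}
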