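"""File formats, configuration and run manifests.

Fixed CSV dialect throughout: comma separator, ``.`` decimal, ISO-8601
dates, UTF-8, LF line endings; missing responses are empty fields.  Every
command-line run writes one JSON manifest linking outputs to the config
hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_response_table",
    "write_response_table",
    "read_person_table",
    "write_person_table",
    "load_config",
    "config_hash",
    "RunManifest",
    "write_manifest",
]

_RESPONSE_COLUMNS = ["person_id", "wave", "item", "response"]


def read_response_table(path) -> pd.DataFrame:
    """Read and validate a long-format ordinal response table.

    Columns: person_id, wave, item, response; an empty response field marks
    a missing (unobserved) item.  Raises on categories outside {0,1,2,3},
    duplicate (person, wave, item) records, and unknown waves, naming the
    offending rows.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _RESPONSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"response table lacks columns {missing_cols}")
    df = df[_RESPONSE_COLUMNS].copy()
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    raw = pd.read_csv(path, dtype=str)["response"]
    bad_parse = df.index[df["response"].isna() & raw.notna() & (raw.str.strip() != "")]
    if len(bad_parse):
        raise ValueError(f"unparseable response values at rows {list(bad_parse[:5])}")
    vals = df["response"].dropna()
    bad = vals[(vals < 0) | (vals > 3) | (vals != vals.round())]
    if len(bad):
        raise ValueError(
            f"responses outside categories 0-3 at rows {list(bad.index[:5])}"
        )
    if (df["wave"] < 0).any():
        raise ValueError("negative wave index")
    dup = df.duplicated(subset=["person_id", "wave", "item"])
    if dup.any():
        raise ValueError(
            f"duplicate (person, wave, item) records at rows {list(df.index[dup][:5])}"
        )
    return df


def write_response_table(df: pd.DataFrame, path):
    out = df[_RESPONSE_COLUMNS].copy()
    out.to_csv(path, index=False, lineterminator="\n")


def read_person_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise ValueError("person table lacks person_id")
    if df["person_id"].duplicated().any():
        raise ValueError("duplicate person_id rows")
    return df


def write_person_table(df: pd.DataFrame, path):
    df.to_csv(path, index=False, lineterminator="\n")


def load_config(path) -> dict:
    """Flat YAML/JSON key-value configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""
    config_sha: str = ""


def write_manifest(out_dir, command, config=None, seed=None, inputs=(), outputs=()):
    """Write the run manifest JSON next to the outputs; returns its path."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or {}
    manifest = RunManifest(
        command=command,
        config=cfg,
        seed=seed,
        inputs=[str(p) for p in inputs],
        outputs=[str(p) for p in outputs],
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config_sha=config_hash(cfg),
    )
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
    return path
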