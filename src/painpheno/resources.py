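"""Access to packaged data tables (lexicons, mappings, manifest)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

_DATA = resources.files("painpheno") / "data"


def data_path(name: str) -> Path:
    """Return a filesystem path to a packaged data file."""
    path = Path(str(_DATA / name))
    if not path.exists():
        raise FileNotFoundError(f"packaged data file not found: {name}")
    return path


def read_table(name: str) -> pd.DataFrame:
    """Read a packaged tab-delimited table."""
    return pd.read_csv(data_path(name), sep="\t", dtype=str)


def load_stopwords() -> frozenset[str]:
    text = data_path("stopwords.txt").read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())
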