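"""TSV reading/writing with provenance headers.

All tables are tab-separated text. Written files carry ``#``-prefixed
header comments (package version, seed, config hash) so every output is
traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .preprocess import OmicsBlock
from .simulate import OTUTable


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                index_label: str | None = None,
                provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seafusion {__version__}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_design(design: pd.DataFrame, path: str | Path,
                 provenance: dict | None = None) -> Path:
    return write_table(design, path, provenance=provenance)


def read_design(path: str | Path) -> pd.DataFrame:
    return read_table(path)


def write_block(block: OmicsBlock, path: str | Path,
                provenance: dict | None = None) -> Path:
    return write_table(block.data, path, index_label="sample_id",
                       provenance=provenance)


def read_block(path: str | Path, name: str | None = None) -> OmicsBlock:
    data = read_table(path, index_col="sample_id")
    return OmicsBlock(name=name or Path(path).stem, data=data)


def write_otu(table: OTUTable, path: str | Path,
              provenance: dict | None = None) -> Path:
    out = table.counts.copy()
    out.insert(0, "taxonomy", table.taxonomy)
    return write_table(out, path, index_label="taxon_id",
                       provenance=provenance)


def read_otu(path: str | Path) -> OTUTable:
    raw = read_table(path, index_col="taxon_id")
    taxonomy = raw.pop("taxonomy")
    return OTUTable(counts=raw.astype(int), taxonomy=taxonomy)
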