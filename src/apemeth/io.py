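"""On-disk formats: TSV/CSV tables with a provenance header line,
multi-FASTA alignments, Newick trees and JSON reports.

Every table written by a pipeline run starts with a comment line
``# apemeth config=<hash> seed=<seed>`` so outputs are traceable to
the exact configuration that produced them; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# apemeth {parts}\n"


def write_table(
    df: pd.DataFrame, path, sep: str = "\t", meta: dict | None = None, index: bool = True
):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, sep=sep, index=index, lineterminator="\n")


def read_table(path, sep: str = "\t", index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def write_json(obj, path, meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"meta": meta or {}, "data": obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def write_probe_list(ids, path, meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        for pid in ids:
            fh.write(f"{pid}\n")


def read_probe_list(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_fasta_blocks(blocks, path):
    """Write alignment blocks as multi-FASTA; block b, taxon t becomes
    record ``>t|block=b``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for b, block in enumerate(blocks):
            for taxon in sorted(block):
                fh.write(f">{taxon}|block={b}\n{block[taxon]}\n")


def read_fasta_blocks(path) -> list[dict]:
    blocks: dict[int, dict] = {}
    name, buf = None, []

    def flush():
        if name is None:
            return
        taxon, tag = name.split("|block=")
        blocks.setdefault(int(tag), {})[taxon] = "".join(buf)

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            flush()
            name, buf = line[1:].strip(), []
        elif line.strip():
            buf.append(line.strip())
    flush()
    return [blocks[k] for k in sorted(blocks)]


def write_newick(tree, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(str(tree).strip() + "\n")
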