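"""Delimited-text tables with a schema-version header line.

Every stage output is a flat CSV preceded by a single comment line

    # warmgrowth-table: <name> v<version> seed=<seed> config=<hash>

so users can substitute real data for any stage while keeping provenance.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMA_VERSION = 1


def write_table(
    df: pd.DataFrame, path, name: str, seed: int | None = None, config_hash: str = ""
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# warmgrowth-table: {name} v{SCHEMA_VERSION}"
    if seed is not None:
        header += f" seed={seed}"
    if config_hash:
        header += f" config={config_hash}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
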