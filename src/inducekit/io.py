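"""Plain-text I/O: long TSV cubes, spot tables, edge lists, GMT, JSON ledgers."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import EXP, GENE, TIME, VALUE, ExpressionCube, TrueNetwork


def write_cube(cube: ExpressionCube, path, log2: bool = False) -> None:
    cube.to_long(log2=log2).to_csv(path, sep="\t", index=False)


def read_cube(path, log2: bool = False) -> ExpressionCube:
    long = pd.read_csv(path, sep="\t")
    missing = {GENE, EXP, TIME, VALUE} - set(long.columns)
    if missing:
        raise ValueError(f"cube TSV lacks columns: {sorted(missing)}")
    return ExpressionCube.from_long(long, log2=log2)


def write_spots(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def read_spots(path) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t")
    missing = {GENE, EXP, TIME, "spot_index", "red", "green"} - set(spots.columns)
    if missing:
        raise ValueError(f"spot TSV lacks columns: {sorted(missing)}")
    return spots


def write_network(network: TrueNetwork, path) -> None:
    network.to_frame().to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list[tuple]:
    """Two-column (or wider) TSV of undirected reference edges."""
    table = pd.read_csv(path, sep="\t")
    cols = list(table.columns[:2])
    return list(zip(table[cols[0]], table[cols[1]]))


def read_class_map(path) -> dict:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def write_ledger(ledger: dict, path) -> None:
    Path(path).write_text(json.dumps(ledger, indent=2))


def read_ledger(path) -> dict:
    return json.loads(Path(path).read_text())


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> member genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets
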