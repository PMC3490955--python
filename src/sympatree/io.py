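"""Readers and writers for the pipeline's external formats.

Newick chronograms (single- and multi-tree, one per line), the locality CSV
dialect (``species,latitude,longitude[,site]``, decimal degrees, WGS84
assumed), and the TSV/JSON outputs of each analysis stage.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .chronogram import Chronogram
from .geo import LocalityTable

log = logging.getLogger("sympatree")

__all__ = [
    "read_chronogram",
    "read_posterior_trees",
    "read_localities",
    "write_json",
    "write_tsv",
]


def read_chronogram(
    path, tol: float = 1e-6, outgroup: list[str] | None = None
) -> Chronogram:
    """Parse and validate a Newick chronogram; optionally prune outgroups."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chron = Chronogram.from_path(str(path), tol=tol)
    if outgroup:
        chron = chron.drop_tips(outgroup)
        log.info("pruned outgroup tips: %s", sorted(outgroup))
    log.info(
        "chronogram: %d tips, crown age %.4g Myr", chron.n_tips,
        chron.crown_age,
    )
    return chron


def read_posterior_trees(
    path, tol: float = 1e-6, outgroup: list[str] | None = None
) -> list[Chronogram]:
    """One Newick tree per non-empty line."""
    path = Path(path)
    trees = []
    for k, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        try:
            chron = Chronogram.from_newick(line, tol=tol)
        except Exception as exc:
            raise ValueError(f"{path}:{k + 1}: {exc}") from exc
        if outgroup:
            chron = chron.drop_tips(outgroup)
        trees.append(chron)
    if not trees:
        raise ValueError(f"{path}: no trees found")
    return trees


def read_localities(path) -> LocalityTable:
    """Locality CSV with header species,latitude,longitude[,site]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"species", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    rows = []
    for k, row in df.iterrows():
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: row {k + 2}: unparseable coordinate"
            ) from exc
        try:
            rows.append((str(row["species"]), lat, lon))
            LocalityTable.from_records(rows[-1:])
        except ValueError as exc:
            raise ValueError(f"{path}: row {k + 2}: {exc}") from exc
    table = LocalityTable.from_records(rows)
    for sp, n in sorted(table.counts().items()):
        log.info("localities: %s has %d record(s)", sp, n)
    return table


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
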