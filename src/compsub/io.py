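"""File round-tripping for replicates, events, rates, summaries and Q matrices.

Every artifact embeds the fully resolved configuration and base seed (as
``# key = value`` header comments in TSV, as a ``config`` block in JSON), so
a result file alone suffices to reproduce the run bit-identically.  No
timestamps are written, keeping reruns byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .model import Haplotype
from .rates import RateSet
from .simulate import FixationEvent, ReplicateRecord

__all__ = [
    "write_replicates_tsv",
    "read_replicates_tsv",
    "write_events_tsv",
    "write_rates_json",
    "read_rates_json",
    "write_summary_json",
    "write_qmatrix_tsv",
]

REPLICATE_COLUMNS = [
    "replicate_id", "seed", "pathway_type", "censored", "n_fixation_events",
    "n_reversions", "total_generations", "final_path_generations",
]


def _header_lines(config: RunConfig | None) -> list[str]:
    lines = [f"# compsub_version = {__version__}"]
    if config is not None:
        for key, value in config.to_dict().items():
            lines.append(f"# {key} = {value}")
    return lines


def write_replicates_tsv(records: list[ReplicateRecord], path: str | Path,
                         config: RunConfig | None = None) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPLICATE_COLUMNS)
        for r in records:
            writer.writerow([
                r.replicate_id, r.seed,
                r.pathway_type if r.pathway_type is not None else "NA",
                int(r.censored), len(r.events), r.reversion_count,
                r.total_generations, r.final_path_generations,
            ])


def read_replicates_tsv(path: str | Path) -> pd.DataFrame:
    # keep_default_na=False so the censored-pathway marker "NA" survives as
    # a string instead of silently becoming NaN
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     dtype={"pathway_type": "object"})
    df["pathway_type"] = df["pathway_type"].map(
        lambda v: None if v in ("NA", "", None) else int(v)
    )
    df["censored"] = df["censored"].astype(int).astype(bool)
    return df


def write_events_tsv(records: list[ReplicateRecord], path: str | Path,
                     config: RunConfig | None = None) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["replicate_id", "generation", "haplotype"])
        for r in records:
            for e in r.events:
                writer.writerow([r.replicate_id, e.generation, e.haplotype.name])


def _json_payload(body: dict, config: RunConfig | None) -> dict:
    payload = {"compsub_version": __version__}
    if config is not None:
        payload["config"] = config.to_dict()
    payload.update(body)
    return payload


def write_rates_json(rateset: RateSet, path: str | Path,
                     config: RunConfig | None = None) -> None:
    Path(path).write_text(
        json.dumps(_json_payload({"rates": rateset.to_dict()}, config), indent=2) + "\n"
    )


def read_rates_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_summary_json(summary: dict, path: str | Path,
                       config: RunConfig | None = None) -> None:
    Path(path).write_text(
        json.dumps(_json_payload(summary, config), indent=2, allow_nan=True) + "\n"
    )


def write_qmatrix_tsv(Q: np.ndarray, pi: np.ndarray, u: float, mode: str,
                      path: str | Path, config: RunConfig | None = None) -> None:
    labels = [h.name for h in Haplotype]
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write(f"# mode = {mode}\n")
        fh.write(f"# u = {u!r}\n")
        fh.write("# pi = " + "\t".join(repr(float(p)) for p in pi) + "\n")
        fh.write("state\t" + "\t".join(labels) + "\n")
        for i, row_label in enumerate(labels):
            fh.write(row_label + "\t" + "\t".join(repr(float(q)) for q in Q[i]) + "\n")
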