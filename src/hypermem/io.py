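"""Stream and network serialization, plus run configuration.

Event streams travel as TSV/CSV with a header row of attribute names, one
event per row, ``NA`` or an empty field marking a missing value.  Numeric-
looking tokens are canonicalized to ints on read so that a written stream of
integer tokens round-trips identically.

Network snapshots are canonical JSON (sorted edge keys, stable field order):
only link *counts* are stored — weights are derived state and are recomputed
from ``C`` on load, so a snapshot reloaded under a different ``C`` rescales
every weight consistently.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import yaml

from .core import (
    MISSING,
    EdgeConfig,
    EventInstance,
    Hyperedge,
    Hypernetwork,
    Token,
)

__all__ = [
    "read_stream",
    "write_stream",
    "save_network",
    "load_network",
    "RunConfig",
    "load_run_config",
]

SCHEMA_VERSION = 1
_INT_RE = re.compile(r"^-?\d+$")
_NA_TOKENS = ("", "NA")


def _delimiter(path: Union[str, Path]) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _parse_token(tok: str) -> Token:
    if tok in _NA_TOKENS:
        return MISSING
    if _INT_RE.match(tok):
        return int(tok)
    return tok


def _format_token(v: Token) -> str:
    return "NA" if v is MISSING else str(v)


def read_stream(path: Union[str, Path]) -> Tuple[List[EventInstance], List[str]]:
    """Read a TSV/CSV event stream; returns (instances, attribute names)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=_delimiter(path))
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty stream file") from None
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: duplicate attribute names in header")
        d = len(header)
        instances = []
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != d:
                raise ValueError(f"{path}:{ln}: expected {d} fields, got {len(row)}")
            instances.append(EventInstance(_parse_token(t) for t in row))
    if not instances:
        raise ValueError(f"{path}: stream has a header but no events")
    return instances, header


def write_stream(
    path: Union[str, Path],
    instances: Sequence[Sequence[Token]],
    attribute_names: Sequence[str],
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path))
        writer.writerow(attribute_names)
        for inst in instances:
            writer.writerow([_format_token(v) for v in inst])


# ---------------------------------------------------------------------------
# Network snapshots
# ---------------------------------------------------------------------------

def _edge_key(edge: Hyperedge) -> str:
    return json.dumps([list(edge.attrs), [_format_token(v) for v in edge.vals]])


def save_network(network: Hypernetwork, path: Union[str, Path]) -> None:
    """Canonical JSON snapshot: edges per anchor plus link counts."""
    edge_ids = {}
    edges_out = []
    for anchor in range(network.d):
        layer = sorted(network.edges_at(anchor), key=_edge_key)
        for e in layer:
            edge_ids[e] = len(edges_out)
            edges_out.append(
                {"anchor": e.anchor, "attrs": list(e.attrs), "vals": list(e.vals)}
            )
    links_out = sorted(
        [edge_ids[ea], edge_ids[eb], count]
        for (ea, eb), count in network._links.items()
    )
    doc = {
        "schema_version": SCHEMA_VERSION,
        "d": network.d,
        "topology": network.topology,
        "C": network.C,
        "attribute_names": network.attribute_names,
        "n_encoded": network.n_encoded,
        "encoded_instances": sorted(
            [list(inst) for inst in network.encoded_set], key=repr
        ),
        "edges": edges_out,
        "links": links_out,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


def load_network(path: Union[str, Path], C: Optional[float] = None) -> Hypernetwork:
    """Rebuild a network from a snapshot; ``C`` overrides the stored constant.

    Counts are reconstructed exactly; weights are recomputed from the
    (possibly overridden) ``C``.
    """
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported network schema version {version!r}")
    net = Hypernetwork(
        doc["d"],
        doc["topology"],
        C if C is not None else doc["C"],
        doc["attribute_names"],
    )
    edges = []
    for e in doc["edges"]:
        edge = Hyperedge(int(e["anchor"]), tuple(e["attrs"]), tuple(e["vals"]))
        net._add_edge(edge)
        edges.append(edge)
    for a, b, count in doc["links"]:
        ea, eb = edges[a], edges[b]
        net._bump_link(ea, eb)
        net._links[(ea, eb)] = int(count)
    net.n_encoded = int(doc["n_encoded"])
    for inst in doc["encoded_instances"]:
        key = tuple(inst)
        net.encoded_set.add(key)
        for i, v in enumerate(key):
            net.observed_alphabets[i].add(v)
    return net


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Mirror of :class:`EdgeConfig` plus the run-level knobs a CLI needs."""

    mode: str = "fixed"
    k: Optional[int] = None
    order_range: Optional[Tuple[int, int]] = None
    topology: str = "ring"
    repetitions: int = 1
    observation_count: int = 1
    C: float = 10.0
    N_m: int = 0
    seed: int = 0
    section_size: int = 1000
    n_missing: int = 3
    encodings: int = 5
    observations: int = 5
    update_interval: int = 1000

    def edge_config(self) -> EdgeConfig:
        return EdgeConfig(
            mode=self.mode,
            k=self.k,
            order_range=tuple(self.order_range) if self.order_range else None,
            topology=self.topology,
            repetitions=self.repetitions,
            observation_count=self.observation_count,
        )


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Load a JSON or YAML run configuration (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "order_range" in data and data["order_range"] is not None:
        data["order_range"] = tuple(data["order_range"])
    return RunConfig(**data)
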