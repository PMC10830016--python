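"""Reading and writing tripartite networks.

Two dialects are supported:

* **edgelist** — a TSV with header ``layer  resource  consumer`` and an
  optional ``weight`` column, plus a companion metadata file (YAML or JSON)
  declaring the three species sets and, per layer, the sign and orientation.
  By default the metadata file sits next to the edge file as
  ``<stem>.meta.yaml`` (or ``.meta.json``).
* **incidence** — the metadata file itself is loaded; each layer entry names
  a CSV matrix (rows = resource species, columns = consumer species,
  entries 0 or the interaction weight) via a ``matrix`` key, resolved
  relative to the metadata file.

The writer emits the edgelist dialect deterministically (layers in
declaration order, edges sorted lexicographically), so write → read → write
is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError
from .model import Edge, Layer, SpeciesSet, TripartiteNetwork

PathLike = Union[str, Path]

_EDGE_COLUMNS = ("layer", "resource", "consumer")


def _read_metadata(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        try:
            return json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON metadata: {exc}") from exc
    try:
        meta = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML metadata: {exc}") from exc
    if not isinstance(meta, dict):
        raise ParseError(f"{path}: metadata must be a mapping")
    return meta


def _metadata_path(edge_path: Path) -> Path:
    for suffix in (".meta.yaml", ".meta.yml", ".meta.json"):
        cand = edge_path.with_suffix(suffix)
        if cand.exists():
            return cand
    raise ConfigurationError(
        f"no metadata file found next to {edge_path} "
        "(expected <stem>.meta.yaml or <stem>.meta.json)"
    )


def _sets_from_meta(meta: dict) -> list[SpeciesSet]:
    raw = meta.get("sets")
    if not raw:
        raise ParseError("metadata: missing 'sets'")
    sets = []
    if isinstance(raw, dict):  # mapping form: name -> members
        items = raw.items()
    else:
        items = [(d["name"], d["members"]) for d in raw]
    for name, members in items:
        sets.append(SpeciesSet(name=str(name), members=tuple(str(m) for m in members)))
    return sets


def _drop_isolated(
    sets: list[SpeciesSet], layers: list[Layer]
) -> list[SpeciesSet]:
    linked = {n for layer in layers for e in layer.edges for n in e}
    out = []
    for s in sets:
        keep = tuple(m for m in s.members if m in linked)
        dropped = [m for m in s.members if m not in linked]
        if dropped:
            warnings.warn(
                f"set {s.name!r}: dropping {len(dropped)} isolated species "
                f"(no links in either layer): {dropped[:5]}",
                stacklevel=3,
            )
        out.append(SpeciesSet(name=s.name, members=keep))
    return out


def load_network(
    path: PathLike,
    format: str = "edgelist",
    metadata: Optional[PathLike] = None,
    drop_isolated: bool = True,
) -> TripartiteNetwork:
    """Load a tripartite network from disk.

    Parameters
    ----------
    path
        The edge-list TSV (``format="edgelist"``) or the metadata file
        (``format="incidence"``).
    metadata
        Explicit metadata path for the edgelist dialect; defaults to the
        companion ``<stem>.meta.yaml`` / ``.meta.json``.
    drop_isolated
        Drop species with zero links in both layers, with a warning.
        Source matrices sometimes carry such species; they contribute
        nothing to connectivity or extinction dynamics but would inflate
        set sizes.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    if format == "edgelist":
        meta_path = Path(metadata) if metadata else _metadata_path(path)
        meta = _read_metadata(meta_path)
        layers = _load_edgelist_layers(path, meta)
    elif format == "incidence":
        meta = _read_metadata(path)
        layers = _load_incidence_layers(path.parent, meta)
    else:
        raise ConfigurationError(f"unknown format {format!r}")
    sets = _sets_from_meta(meta)
    if drop_isolated:
        sets = _drop_isolated(sets, layers)
    return TripartiteNetwork(sets=sets, layers=layers, name=str(meta.get("name", "")))


def _layer_decls(meta: dict) -> list[dict]:
    raw = meta.get("layers")
    if not raw or len(raw) != 2:
        raise ParseError("metadata: 'layers' must declare exactly 2 layers")
    return list(raw)


def _load_edgelist_layers(path: Path, meta: dict) -> list[Layer]:
    decls = _layer_decls(meta)
    by_name = {str(d["name"]): d for d in decls}
    edges: dict[str, set[Edge]] = {n: set() for n in by_name}
    weights: dict[str, dict[Edge, float]] = {n: {} for n in by_name}
    has_weight_col = False
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != _EDGE_COLUMNS:
            raise ParseError(
                f"{path}:1: expected header 'layer\\tresource\\tconsumer', got {header}"
            )
        has_weight_col = len(header) > 3 and header[3] == "weight"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            lname, res, con = parts[0], parts[1], parts[2]
            if lname not in edges:
                raise ParseError(f"{path}:{lineno}: undeclared layer {lname!r}")
            e = (res, con)
            if e in edges[lname]:
                raise ParseError(f"{path}:{lineno}: duplicate edge {e} in layer {lname!r}")
            edges[lname].add(e)
            if has_weight_col and len(parts) > 3 and parts[3] != "":
                try:
                    weights[lname][e] = float(parts[3])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: bad weight {parts[3]!r}"
                    ) from None
    layers = []
    for d in decls:
        n = str(d["name"])
        w = weights[n] if weights[n] else None
        if w is not None and len(w) != len(edges[n]):
            raise ParseError(f"layer {n!r}: weights present for only some edges")
        layers.append(
            Layer(
                name=n,
                sign=str(d["sign"]),
                resource_set=str(d["resource_set"]),
                consumer_set=str(d["consumer_set"]),
                edges=frozenset(edges[n]),
                weights=w,
            )
        )
    return layers


def _load_incidence_layers(base: Path, meta: dict) -> list[Layer]:
    layers = []
    for d in _layer_decls(meta):
        matrix_path = base / d["matrix"]
        if not matrix_path.exists():
            raise ConfigurationError(f"no such matrix file: {matrix_path}")
        try:
            mat = pd.read_csv(matrix_path, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{matrix_path}: {exc}") from exc
        weighted = bool(d.get("weighted", False))
        edges: set[Edge] = set()
        weights: dict[Edge, float] = {}
        for res in mat.index:
            for con in mat.columns:
                v = float(mat.loc[res, con])
                if v != 0.0:
                    e = (str(res), str(con))
                    edges.add(e)
                    if weighted:
                        weights[e] = v
        layers.append(
            Layer(
                name=str(d["name"]),
                sign=str(d["sign"]),
                resource_set=str(d["resource_set"]),
                consumer_set=str(d["consumer_set"]),
                edges=frozenset(edges),
                weights=weights if weighted else None,
            )
        )
    return layers


def save_network(net: TripartiteNetwork, path: PathLike) -> tuple[Path, Path]:
    """Write a network in the edgelist dialect; returns (edge path, meta path).

    Output is deterministic: layers in declaration order, edges sorted, so a
    saved file re-saves byte-identically after a round trip.
    """
    path = Path(path)
    meta_path = path.with_suffix(".meta.yaml")
    weighted = any(layer.weights is not None for layer in net.layers)
    lines = ["\t".join(_EDGE_COLUMNS + (("weight",) if weighted else ()))]
    for layer in net.layers:
        for r, c in layer.sorted_edges():
            row = [layer.name, r, c]
            if weighted:
                w = layer.weights[(r, c)] if layer.weights else ""
                row.append(repr(w) if w != "" else "")
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")

    meta = {
        "name": net.name,
        "sets": [
            {"name": s.name, "members": list(s.members)} for s in net.sets
        ],
        "layers": [
            {
                "name": layer.name,
                "sign": layer.sign,
                "resource_set": layer.resource_set,
                "consumer_set": layer.consumer_set,
            }
            for layer in net.layers
        ],
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return path, meta_path
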