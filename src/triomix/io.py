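"""Domain containers and plain-text readers/writers shared by every stage.

All feature matrices are features-as-rows, samples-as-columns, on log2
intensity scale. Missing values are represented as NaN and are only
accepted in the metabolite layer unless explicitly allowed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LAYERS = ("mirna", "protein", "metabolite")

#: layers whose matrices may contain missing entries by default
MISSING_OK_LAYERS = frozenset({"metabolite"})


class TriomixError(ValueError):
    """Raised for invalid inputs anywhere in the pipeline."""


@dataclass
class OmicsMatrix:
    """One omics layer: a feature x sample log2-intensity matrix.

    Parameters
    ----------
    layer
        One of ``mirna``, ``protein``, ``metabolite``.
    feature_ids, sample_ids
        Unique row / column identifiers.
    values
        ``(n_features, n_samples)`` float array; NaN marks a missing entry.
    """

    layer: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    allow_missing: bool | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise TriomixError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TriomixError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.allow_missing is None:
            self.allow_missing = self.layer in MISSING_OK_LAYERS
        if not self.allow_missing and np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise TriomixError(
                f"layer {self.layer!r} does not permit missing values "
                f"(first at feature {self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}); "
                "impute first or construct with allow_missing=True"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return dataclasses.replace(
            self, sample_ids=list(sample_ids), values=self.values[:, idx]
        )

    def subset_features(self, feature_ids: list[str]) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return dataclasses.replace(
            self, feature_ids=list(feature_ids), values=self.values[idx, :]
        )


@dataclass
class SampleMetadata:
    """Ordered mapping of sample id to group label."""

    group_of: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_of)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def check_matrix(self, matrix: OmicsMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.group_of]
        if missing:
            raise TriomixError(f"samples absent from metadata: {missing}")


@dataclass(frozen=True)
class Contrast:
    """Two-group comparison; positive effects mean higher in ``group_b``."""

    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise TriomixError("contrast groups must differ")

    def validate(self, meta: SampleMetadata, min_per_group: int = 3) -> None:
        for g in (self.group_a, self.group_b):
            n = len(meta.samples_in(g))
            if n == 0:
                raise TriomixError(f"group {g!r} not present in metadata")
            if n < min_per_group:
                raise TriomixError(
                    f"group {g!r} has {n} samples; >= {min_per_group} required "
                    "for variance estimation"
                )


@dataclass
class PathwayDef:
    """A pathway: member compound ids plus an undirected topology graph."""

    pathway_id: str
    name: str
    members: set[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise TriomixError(f"pathway {self.pathway_id}: self-loop on {a!r}")
            for node in (a, b):
                if node not in self.members:
                    raise TriomixError(
                        f"pathway {self.pathway_id}: edge endpoint {node!r} is not a member"
                    )


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise TriomixError(f"duplicate {kind} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_feature_matrix(path: str | Path, layer: str) -> OmicsMatrix:
    """Read a CSV/TSV feature matrix (first column ids, header sample ids).

    Blank cells become NaN. Values are taken as-is; the caller declares the
    scale. Duplicated ids or non-numeric cells raise with coordinates.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    feature_ids = [str(i) for i in raw.index]
    sample_ids = [str(c) for c in raw.columns]
    _check_unique(feature_ids, "feature")
    _check_unique(sample_ids, "sample")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise TriomixError(
                f"non-numeric cell {raw[col].iloc[i]!r} at feature "
                f"{feature_ids[i]!r}, sample {sample_ids[j]!r} in {path}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return OmicsMatrix(layer=layer, feature_ids=feature_ids, sample_ids=sample_ids, values=values)


def write_feature_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as CSV/TSV (by suffix); round-trips values to <1e-9."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep, float_format="%.12g", lineterminator="\n")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read a two-column TSV (sample_id, group); file order preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TriomixError(f"{path}: expected two columns (sample_id, group)")
    mapping: dict[str, str] = {}
    for s, g in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if s in mapping:
            raise TriomixError(f"sample {s!r} listed twice in {path}")
        mapping[str(s)] = str(g)
    return SampleMetadata(group_of=mapping)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in meta.group_of.items():
            fh.write(f"{s}\t{g}\n")


def load_pathway_library(gmt_path: str | Path, edges_path: str | Path | None = None) -> list[PathwayDef]:
    """Load a GMT membership file plus an optional per-pathway edge list.

    GMT lines: ``pathway_id<TAB>name<TAB>member...``. Edge lines:
    ``pathway_id<TAB>member_a<TAB>member_b``. Pathways without edge lines get
    an empty topology; an edge naming a non-member is a hard error.
    """
    pathways: dict[str, PathwayDef] = {}
    with open(gmt_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TriomixError(f"GMT line needs id, name and >=1 member: {line!r}")
            pid, name, members = parts[0], parts[1], parts[2:]
            if pid in pathways:
                raise TriomixError(f"duplicate pathway id {pid!r}")
            pathways[pid] = PathwayDef(pathway_id=pid, name=name, members=set(members))
    if edges_path is not None:
        with open(edges_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                pid, a, b = line.split("\t")[:3]
                if pid not in pathways:
                    raise TriomixError(f"edge references unknown pathway {pid!r}")
                pw = pathways[pid]
                for node in (a, b):
                    if node not in pw.members:
                        raise TriomixError(
                            f"pathway {pid!r}: edge node {node!r} is not a member"
                        )
                pw.edges.append((a, b))
    return list(pathways.values())


# ---------------------------------------------------------------------------
# network/edge writers (deterministic, byte-comparable)
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ("feat_a", "layer_a", "feat_b", "layer_b", "r", "p", "n")


def write_edge_list(edges, path: str | Path) -> None:
    """Write cross-layer edges as TSV with fixed 6-decimal formatting."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in edges:
            fh.write(
                f"{e.feat_a}\t{e.layer_a}\t{e.feat_b}\t{e.layer_b}\t"
                f"{e.r:.6f}\t{e.p:.6f}\t{e.n}\n"
            )


def write_network(edges, path: str | Path) -> None:
    """Write the cross-layer network as GraphML; nodes carry a 'layer' attribute."""
    import networkx as nx

    g = nx.Graph()
    nodes = sorted({(e.feat_a, e.layer_a) for e in edges} | {(e.feat_b, e.layer_b) for e in edges})
    for feat, layer in nodes:
        g.add_node(feat, layer=layer)
    for e in sorted(edges, key=lambda e: (e.layer_a, e.layer_b, e.feat_a, e.feat_b)):
        g.add_edge(e.feat_a, e.feat_b, r=round(float(e.r), 6), p=round(float(e.p), 6), n=int(e.n))
    nx.write_graphml(g, path)
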