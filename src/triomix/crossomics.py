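"""Cross-layer correlation integration and hub ranking.

Every cross-layer pair among the per-layer significant features gets a
Pearson correlation over the shared (matched) samples; edges are filtered
on |r| and p (sign retained), and miRNA-side hubs are ranked by degree,
then mean |r|, then id. Correlations default to spanning all profiled
samples: treatment-induced covariation is the object of interest, and the
feature lists — not the correlation scope — carry the contrast.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import OmicsMatrix, SampleMetadata, TriomixError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossEdge:
    """A cross-layer association; layer_a < layer_b lexicographically."""

    feat_a: str
    layer_a: str
    feat_b: str
    layer_b: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.layer_a == self.layer_b:
            raise TriomixError("cross edges must join different layers")
        if self.layer_a > self.layer_b:
            raise TriomixError("edge layers must be in canonical (lexicographic) order")
        if not -1.0000001 <= self.r <= 1.0000001:
            raise TriomixError(f"invalid correlation {self.r}")
        if self.n < 3:
            raise TriomixError("edges need n >= 3 complete sample pairs")


@dataclass
class HubRanking:
    mirna_id: str
    degree: int
    mean_abs_r: float
    partners: list[str] = field(default_factory=list)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float | None, int]:
    """Sample Pearson correlation with pairwise-complete deletion.

    Returns ``(r, n)`` where n is the number of complete pairs used.
    ``r`` is None (flagged not-computable) for constant vectors or n < 3.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise TriomixError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return None, n
    xs, ys = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    sx, sy = np.sqrt(xs @ xs), np.sqrt(ys @ ys)
    if sx == 0 or sy == 0:
        return None, n
    return float(np.clip(xs @ ys / (sx * sy), -1.0, 1.0)), n


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r*sqrt(n-2)/sqrt(1-r^2), t(n-2)."""
    if not -1 <= r <= 1:
        raise TriomixError(f"|r| must be <= 1, got {r}")
    if n < 3:
        raise TriomixError("n must be >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


def correlate_layers(
    sig_features: dict[str, list[str]],
    matrices: dict[str, OmicsMatrix],
    meta: SampleMetadata | None = None,
    samples: list[str] | None = None,
) -> list[CrossEdge]:
    """All cross-layer Pearson edges among significant features.

    ``samples`` restricts the correlation scope (e.g. to the two contrast
    groups); default is every sample shared by the involved matrices,
    which must be matched one-to-one across layers. Pairs whose
    correlation is not computable (constant vector, < 3 complete pairs)
    are skipped with a log message.
    """
    layers = sorted(k for k, feats in sig_features.items() if feats)
    if len(layers) < 2:
        log.info("fewer than two layers carry significant features; no edges to test")
        return []
    for layer in layers:
        if layer not in matrices:
            raise TriomixError(f"no matrix supplied for layer {layer!r}")
    if samples is None:
        samples = list(matrices[layers[0]].sample_ids)
    for layer in layers:
        missing = [s for s in samples if s not in matrices[layer].sample_ids]
        if missing:
            raise TriomixError(
                f"samples missing from the {layer} matrix (layers must be matched): {missing}"
            )
    subs = {
        layer: matrices[layer].subset_samples(samples).subset_features(sorted(set(sig_features[layer])))
        for layer in layers
    }
    edges: list[CrossEdge] = []
    n_skipped = 0
    for la, lb in itertools.combinations(layers, 2):
        A, B = subs[la], subs[lb]
        for i, fa in enumerate(A.feature_ids):
            for j, fb in enumerate(B.feature_ids):
                r, n = pearson_r(A.values[i], B.values[j])
                if r is None:
                    n_skipped += 1
                    continue
                edges.append(
                    CrossEdge(feat_a=fa, layer_a=la, feat_b=fb, layer_b=lb,
                              r=r, p=pearson_p(r, n), n=n)
                )
    if n_skipped:
        log.info("%d pairs had no computable correlation and were skipped", n_skipped)
    edges.sort(key=lambda e: (e.layer_a, e.layer_b, e.feat_a, e.feat_b))
    return edges


def filter_edges(edges: list[CrossEdge], r_min: float = 0.9, p_max: float = 0.05) -> list[CrossEdge]:
    """Keep edges with |r| >= r_min and p <= p_max; sign is preserved."""
    return [e for e in edges if abs(e.r) >= r_min and e.p <= p_max]


def rank_hubs(edges: list[CrossEdge]) -> list[HubRanking]:
    """Rank miRNA-side features by degree desc, mean |r| desc, id asc."""
    by_mirna: dict[str, list[CrossEdge]] = {}
    for e in edges:
        if e.layer_a == "mirna":
            by_mirna.setdefault(e.feat_a, []).append(e)
        elif e.layer_b == "mirna":
            by_mirna.setdefault(e.feat_b, []).append(e)
    hubs = [
        HubRanking(
            mirna_id=m,
            degree=len(es),
            mean_abs_r=float(np.mean([abs(e.r) for e in es])),
            partners=sorted(
                e.feat_b if e.layer_a == "mirna" else e.feat_a for e in es
            ),
        )
        for m, es in by_mirna.items()
    ]
    hubs.sort(key=lambda h: (-h.degree, -h.mean_abs_r, h.mirna_id))
    return hubs
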