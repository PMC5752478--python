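"""End-to-end orchestration of the tri-omics analysis on simulated data.

``run_all`` chains every stage — simulation, per-layer differential
expression, OPLS-DA/VIP metabolite selection, pathway analysis, and
cross-layer correlation integration — and (optionally) writes
deterministic, byte-comparable tables. It returns the in-memory results
so the stages can also be used programmatically.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import crossomics, diffexpr, pathways
from .config import RunConfig
from .io import Contrast, OmicsMatrix, SampleMetadata, write_edge_list, write_network
from .simulate import SimConfig, TriomicsTruth, generate_triomics

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


@dataclass
class PipelineResult:
    matrices: dict[str, OmicsMatrix]
    meta: SampleMetadata
    truth: TriomicsTruth | None
    de: dict[str, pd.DataFrame]
    sig: dict[str, list[str]]
    vip_table: pd.DataFrame
    opls_summary: dict[str, float]
    pathway_table: pd.DataFrame
    edges: list
    filtered_edges: list = field(default_factory=list)
    hubs: list = field(default_factory=list)


def significant_ids(de_table: pd.DataFrame) -> list[str]:
    """Feature ids called up or down, in table (p-ranked) order."""
    mask = de_table["direction"] != "ns"
    return de_table.loc[mask, "feature_id"].tolist()


def metabolite_stage(
    matrix: OmicsMatrix,
    meta: SampleMetadata,
    contrast: Contrast,
    cfg: RunConfig,
    spec: chem.PreprocessSpec | None = None,
    compute_q2: bool = True,
):
    """Preprocess, fit OPLS-DA, score VIP, select, and secondary-test.

    Selection is VIP > cfg.vip_min followed by a Welch test (p < cfg.p_de)
    on the selected features — the secondary univariate confirmation that
    trims a VIP list down to the significantly changed metabolites.
    """
    contrast.validate(meta)
    spec = spec or chem.PreprocessSpec()
    pre = chem.preprocess(matrix, spec)
    samples = [
        s for s in pre.sample_ids
        if meta.group_of[s] in (contrast.group_a, contrast.group_b)
    ]
    sub = pre.subset_samples(samples)
    X = sub.values.T  # samples x features
    y = chem.class_vector(samples, meta.group_of, contrast.group_a, contrast.group_b)
    model = chem.opls(X, y, n_ortho=cfg.n_orthogonal)
    vip_scores = chem.vip(model)
    q2 = chem.q2_cv(X, y, n_ortho=cfg.n_orthogonal, folds=cfg.cv_folds, seed=cfg.seed) if compute_q2 else float("nan")
    selected = chem.select_by_vip(vip_scores, sub.feature_ids, cfg.vip_min)
    # secondary univariate confirmation: NaN-aware Welch test on the raw
    # log2 matrix (per-feature raw p; the VIP step already did the
    # multivariate screening)
    de_met = diffexpr.run_de(matrix, meta, contrast, cfg, normalization="none")
    pmap = dict(zip(de_met["feature_id"], de_met["p_raw"]))
    confirmed = [f for f in selected if pmap.get(f, 1.0) <= cfg.p_de]
    vip_table = pd.DataFrame({"feature_id": sub.feature_ids, "vip": vip_scores})
    vip_table = vip_table.sort_values(
        ["vip", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    summary = {"R2X": model.r2x, "R2Y": model.r2y, "Q2": q2, "n_ortho": model.n_ortho}
    return model, vip_table, selected, confirmed, summary, de_met


def run_all(
    sim_cfg: SimConfig | None = None,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
    contrast: Contrast | None = None,
    compute_q2: bool = True,
) -> PipelineResult:
    """Simulate a tri-omics dataset and run the full analysis.

    The default contrast compares the injury model against the treated
    group. With ``out_dir`` set, all stage outputs are written as
    fixed-format TSV/GraphML/JSON so repeated runs are byte-identical.
    """
    sim_cfg = sim_cfg or SimConfig()
    cfg = cfg or RunConfig()
    if contrast is None:
        if len(sim_cfg.groups) < 2:
            raise ValueError("need at least two groups")
        contrast = Contrast(group_a=sim_cfg.groups[-2], group_b=sim_cfg.groups[-1])
    matrices, meta, truth = generate_triomics(sim_cfg)

    de = {
        layer: diffexpr.run_de(matrices[layer], meta, contrast, cfg)
        for layer in ("mirna", "protein")
    }
    _, vip_table, selected, confirmed, summary, de_met = metabolite_stage(
        matrices["metabolite"], meta, contrast, cfg, compute_q2=compute_q2
    )
    de["metabolite"] = de_met
    sig = {
        "mirna": significant_ids(de["mirna"]),
        "protein": significant_ids(de["protein"]),
        "metabolite": confirmed,
    }

    library = pathways.load_bundled_library()
    compounds = {m for pw in library for m in pw.members}
    universe = compounds & set(matrices["metabolite"].feature_ids)
    hits = set(confirmed) & universe
    pathway_table = pathways.analyze_pathways(hits, library, universe, cfg)

    edges = crossomics.correlate_layers(sig, matrices, meta)
    filtered = crossomics.filter_edges(edges, cfg.r_min, cfg.p_edge_max)
    hubs = crossomics.rank_hubs(filtered)

    result = PipelineResult(
        matrices=matrices, meta=meta, truth=truth, de=de, sig=sig,
        vip_table=vip_table, opls_summary=summary, pathway_table=pathway_table,
        edges=edges, filtered_edges=filtered, hubs=hubs,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def hubs_frame(hubs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna_id": h.mirna_id, "degree": h.degree, "mean_abs_r": h.mean_abs_r,
             "partners": ";".join(h.partners)}
            for h in hubs
        ],
        columns=["mirna_id", "degree", "mean_abs_r", "partners"],
    )


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for layer, table in result.de.items():
        table.to_csv(out_dir / f"de_{layer}.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT, lineterminator="\n")
        sig_tab = table[table["direction"] != "ns"]
        sig_tab.to_csv(out_dir / f"de_{layer}_significant.tsv", sep="\t", index=False,
                       float_format=FLOAT_FMT, lineterminator="\n")
    result.vip_table.to_csv(out_dir / "vip_metabolite.tsv", sep="\t", index=False,
                            float_format=FLOAT_FMT, lineterminator="\n")
    result.pathway_table.to_csv(out_dir / "pathways.tsv", sep="\t", index=False,
                                float_format=FLOAT_FMT, lineterminator="\n")
    write_edge_list(result.filtered_edges, out_dir / "edges.tsv")
    write_network(result.filtered_edges, out_dir / "network.graphml")
    hubs_frame(result.hubs).to_csv(out_dir / "hubs.tsv", sep="\t", index=False,
                                   float_format=FLOAT_FMT, lineterminator="\n")
    with open(out_dir / "opls_summary.json", "w") as fh:
        import json

        json.dump({k: (round(float(v), 6) if isinstance(v, float) else v)
                   for k, v in result.opls_summary.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if result.truth is not None:
        result.truth.to_json(out_dir / "truth.json")


# ---------------------------------------------------------------------------
# truth-recovery summaries (used by the acceptance machinery and examples)
# ---------------------------------------------------------------------------

def recovery_summary(result: PipelineResult, layers=("mirna", "protein")) -> dict[str, float]:
    """Joint planted-truth recovery and false-discovery proportion."""
    truth = result.truth
    if truth is None:
        raise ValueError("pipeline was run without ground truth")
    planted: set[tuple[str, str]] = set()
    called: set[tuple[str, str]] = set()
    for layer in layers:
        planted |= {(layer, f) for f in truth.planted(layer)}
        called |= {(layer, f) for f in significant_ids(result.de[layer])}
    tp = len(planted & called)
    fp = len(called - planted)
    return {
        "recovery": tp / len(planted) if planted else float("nan"),
        "fdp": fp / len(called) if called else 0.0,
        "n_called": len(called),
        "n_planted": len(planted),
    }


def block_edge_stats(result: PipelineResult) -> dict[str, float]:
    """Check that every planted within-block cross-layer pair survived the filter."""
    truth = result.truth
    if truth is None or not truth.blocks:
        return {"n_expected": 0, "n_found": 0, "min_abs_r": float("nan")}
    kept = {
        frozenset([(e.layer_a, e.feat_a), (e.layer_b, e.feat_b)]): abs(e.r)
        for e in result.filtered_edges
    }
    expected, found, rs = 0, 0, []
    for block in truth.blocks:
        feats = block.all_features()
        for (fa, la, _), (fb, lb, _) in itertools.combinations(feats, 2):
            if la == lb:
                continue
            expected += 1
            key = frozenset([(la, fa), (lb, fb)])
            if key in kept:
                found += 1
                rs.append(kept[key])
    return {
        "n_expected": expected,
        "n_found": found,
        "min_abs_r": float(np.min(rs)) if rs else float("nan"),
    }


def hub_rank(result: PipelineResult) -> int | None:
    """1-based rank of the first planted hub among the ranked hubs (None if absent)."""
    truth = result.truth
    if truth is None or not truth.blocks:
        return None
    hub = truth.blocks[0].hub
    for i, h in enumerate(result.hubs, start=1):
        if h.mirna_id == hub:
            return i
    return None
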