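"""Tri-omics simulator with planted ground truth.

The generator emits three log2-scale feature matrices (miRNA, protein,
metabolite) over replicate groups, with

* planted differential features: an additive shift of ±``effect`` log2
  units in the last group (the "treated" condition),
* planted signed cross-layer correlation blocks: a hub miRNA plus partner
  features sharing one latent factor per block, and
* intensity-dependent (left-censoring-like) missingness in the metabolite
  layer.

Block design. Each block's latent factor is
``z_s = alpha * s_g(s) + sqrt(1 - alpha^2) * eta_s`` where ``s_g`` is a
standardized treatment-response pattern (low in the treated group) and
``eta_s`` is i.i.d. standard normal, so z is standard-normal across the
design but carries a between-group component. Members receive
``amplitude * sign * z_s`` with ``amplitude = 3.5 * lam``. Two things
follow by construction: (i) any two members correlate with population
|r| = amplitude^2 / (amplitude^2 + sigma^2) (~0.978 at defaults), and
(ii) every member is itself strongly differentially expressed, because
the same latent factor that couples the block is a treatment response —
the hub's covariation partners co-respond to treatment, which is the
biological situation the block mimics. Truth bookkeeping records block
members inside the planted up/down sets.

A companion generator produces mitochondrial stress-test OCR traces with
known phase plateaus for the assay module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import OmicsMatrix, SampleMetadata, TriomixError

#: multiplier turning the block loading lam into the latent-factor amplitude;
#: chosen so the population within-block |r| clears 0.9 with wide margin
#: (0.978 at lam=0.95, sigma=0.5).
BLOCK_AMPLITUDE_FACTOR = 3.5


@dataclass(frozen=True)
class CorrelationBlock:
    """A hub miRNA plus signed partners sharing one latent factor."""

    hub: str
    members: tuple[tuple[str, str, int], ...]  # (feature_id, layer, sign)
    lam: float = 0.95

    def __post_init__(self) -> None:
        if not self.members:
            raise TriomixError("a block needs >= 1 member besides the hub")
        if not 0 < self.lam <= 1:
            raise TriomixError("lam must be in (0, 1]")

    def all_features(self) -> list[tuple[str, str, int]]:
        return [(self.hub, "mirna", 1)] + list(self.members)


@dataclass
class TriomicsTruth:
    """Planted ground truth emitted alongside the simulated matrices."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]
    blocks: list[CorrelationBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        for layer in self.up:
            if self.up[layer] & self.down.get(layer, set()):
                raise TriomixError(f"up/down sets overlap in layer {layer!r}")

    def planted(self, layer: str) -> set[str]:
        return self.up.get(layer, set()) | self.down.get(layer, set())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "up": {k: sorted(v) for k, v in self.up.items()},
            "down": {k: sorted(v) for k, v in self.down.items()},
            "blocks": [
                {"hub": b.hub, "lam": b.lam, "members": [list(m) for m in b.members]}
                for b in self.blocks
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SimConfig:
    """Study design of the simulated tri-omics experiment.

    Defaults mirror the profiled-data dimensions the pipeline targets:
    1695 miRNAs / 1069 proteins / 2964 metabolite peaks; 18 up + 10 down
    planted miRNAs, 12 + 8 proteins, 9 discriminant metabolites; three
    groups of six replicates. ``effect`` is the planted shift in log2
    units, ``sigma`` the residual standard deviation. One correlation
    block (a hub miRNA tied to two proteins and one metabolite) is
    planted by default; ``block_group_weight`` is the alpha of the
    latent-factor construction described in the module docstring.
    """

    n_mirna: int = 1695
    n_protein: int = 1069
    n_metabolite: int = 2964
    n_per_group: int = 6
    groups: tuple[str, ...] = ("control", "model", "treated")
    mirna_up: int = 18
    mirna_down: int = 10
    protein_up: int = 12
    protein_down: int = 8
    metabolite_up: int = 5
    metabolite_down: int = 4
    effect: float = 2.0
    sigma: float = 0.5
    lam: float = 0.95
    n_blocks: int = 1
    block_group_weight: float = 0.98
    metabolite_missing_rate: float = 0.02
    annotate_metabolites: bool = True
    mu_mean: float = 8.0
    mu_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0 or self.sigma <= 0:
            raise TriomixError("effect must be >= 0 and sigma > 0")
        if not 0 < self.lam <= 1:
            raise TriomixError("lam must be in (0, 1]")
        if not 0 <= self.block_group_weight < 1:
            raise TriomixError("block_group_weight must be in [0, 1)")
        if self.mirna_up + self.mirna_down > self.n_mirna:
            raise TriomixError("planted miRNA count exceeds n_mirna")
        if self.protein_up + self.protein_down > self.n_protein:
            raise TriomixError("planted protein count exceeds n_protein")
        if self.metabolite_up + self.metabolite_down > self.n_metabolite:
            raise TriomixError("planted metabolite count exceeds n_metabolite")
        if not 0 <= self.metabolite_missing_rate < 0.5:
            raise TriomixError("metabolite_missing_rate must be in [0, 0.5)")


#: the nine discriminant compounds planted into the metabolite layer when
#: annotation is on — all members of the bundled TCA-cycle pathway, with
#: oxoglutaric acid first so it serves as the hub's metabolite partner.
PLANTED_COMPOUNDS = (
    "Oxoglutaric acid",
    "Citric acid",
    "Isocitric acid",
    "Succinic acid",
    "Fumaric acid",
    "Malic acid",
    "Oxaloacetic acid",
    "cis-Aconitic acid",
    "Pyruvic acid",
)


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _response_pattern(groups_per_sample: list[str], treated: str) -> np.ndarray:
    """Standardized treatment-response pattern, negative in ``treated``."""
    ind = np.array([1.0 if g == treated else 0.0 for g in groups_per_sample])
    sd = ind.std()
    if sd == 0:
        raise TriomixError("treated group absent; cannot orient blocks")
    return -(ind - ind.mean()) / sd


def generate_triomics(cfg: SimConfig | None = None):
    """Simulate the tri-omics dataset.

    Returns ``(matrices, meta, truth)`` where ``matrices`` maps layer name
    to :class:`OmicsMatrix`. Fully reproducible for a fixed seed; per-layer
    substreams are derived deterministically from it.
    """
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("mirna", "protein", "metabolite", "blocks", "missing", "annotation"),
            ss.spawn(6),
        )
    }

    sample_ids, groups_per_sample = [], []
    for g in cfg.groups:
        for i in range(cfg.n_per_group):
            sample_ids.append(f"{g}_{i + 1}")
            groups_per_sample.append(g)
    meta = SampleMetadata(group_of=dict(zip(sample_ids, groups_per_sample)))
    treated = cfg.groups[-1]
    treated_mask = np.array([g == treated for g in groups_per_sample])
    n_samples = len(sample_ids)

    layer_sizes = {"mirna": cfg.n_mirna, "protein": cfg.n_protein, "metabolite": cfg.n_metabolite}
    planted_counts = {
        "mirna": (cfg.mirna_up, cfg.mirna_down),
        "protein": (cfg.protein_up, cfg.protein_down),
        "metabolite": (cfg.metabolite_up, cfg.metabolite_down),
    }
    prefixes = {"mirna": "miR-", "protein": "prot-", "metabolite": "M"}

    ids: dict[str, list[str]] = {}
    values: dict[str, np.ndarray] = {}
    mus: dict[str, np.ndarray] = {}
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    planted_rows: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    for layer, F in layer_sizes.items():
        rng = streams[layer]
        mu = rng.normal(cfg.mu_mean, cfg.mu_sd, size=F)
        X = mu[:, None] + rng.normal(0.0, cfg.sigma, size=(F, n_samples))
        n_up, n_down = planted_counts[layer]
        chosen = rng.choice(F, size=n_up + n_down, replace=False)
        rows_up, rows_down = chosen[:n_up], chosen[n_up:]
        X[np.ix_(rows_up, np.where(treated_mask)[0])] += cfg.effect
        X[np.ix_(rows_down, np.where(treated_mask)[0])] -= cfg.effect
        ids[layer] = _feature_ids(prefixes[layer], F)
        values[layer] = X
        mus[layer] = mu
        planted_rows[layer] = (rows_up, rows_down)
        up[layer] = {ids[layer][r] for r in rows_up}
        down[layer] = {ids[layer][r] for r in rows_down}

    # annotate metabolite features with library compound names: the planted
    # discriminant peaks become TCA-cycle compounds, the remaining library
    # compounds land on random null peaks
    if cfg.annotate_metabolites:
        from .pathways import load_bundled_library

        rows_up, rows_down = planted_rows["metabolite"]
        planted_order = list(rows_down) + list(rows_up)  # oxoglutaric acid goes down
        met_ids = ids["metabolite"]
        renames: dict[int, str] = {}
        for row, name in zip(planted_order, PLANTED_COMPOUNDS):
            renames[int(row)] = name
        library_compounds = sorted(
            {m for pw in load_bundled_library() for m in pw.members} - set(PLANTED_COMPOUNDS)
        )
        free_rows = np.setdiff1d(np.arange(cfg.n_metabolite), np.array(planted_order))
        chosen_rows = streams["annotation"].choice(free_rows, size=len(library_compounds), replace=False)
        for row, name in zip(chosen_rows, library_compounds):
            renames[int(row)] = name
        met_ids = [renames.get(i, fid) for i, fid in enumerate(met_ids)]
        ids["metabolite"] = met_ids
        up["metabolite"] = {met_ids[r] for r in rows_up}
        down["metabolite"] = {met_ids[r] for r in rows_down}

    # plant correlation blocks: hub = a down-miRNA, partners = two down
    # proteins and one down metabolite, all positively coupled (sign +1)
    blocks: list[CorrelationBlock] = []
    if cfg.n_blocks > 0:
        s = _response_pattern(groups_per_sample, treated)
        amplitude = BLOCK_AMPLITUDE_FACTOR * cfg.lam
        alpha = cfg.block_group_weight
        mir_down = sorted(down["mirna"])
        prot_down = sorted(down["protein"])
        # the oxoglutarate-like compound heads the list so it hosts the
        # first block's metabolite partner when annotation is on
        met_down = sorted(
            down["metabolite"], key=lambda f: (f != PLANTED_COMPOUNDS[0], f)
        )
        if cfg.n_blocks > min(len(mir_down), len(prot_down) // 2, len(met_down)):
            raise TriomixError("not enough planted-down features to host the requested blocks")
        for b in range(cfg.n_blocks):
            hub = mir_down[b]
            members = (
                (prot_down[2 * b], "protein", 1),
                (prot_down[2 * b + 1], "protein", 1),
                (met_down[b], "metabolite", 1),
            )
            block = CorrelationBlock(hub=hub, members=members, lam=cfg.lam)
            eta = streams["blocks"].normal(0.0, 1.0, size=n_samples)
            z = alpha * s + np.sqrt(1.0 - alpha**2) * eta
            for fid, layer, sign in block.all_features():
                row = ids[layer].index(fid)
                # replace the ±effect shift with the block term: the member's
                # differential expression now flows through the latent factor
                values[layer][row] = (
                    mus[layer][row]
                    + sign * amplitude * z
                    + streams[layer].normal(0.0, cfg.sigma, size=n_samples)
                )
            blocks.append(block)

    # intensity-dependent missingness (left-censoring-like) in metabolites
    if cfg.metabolite_missing_rate > 0:
        mu = mus["metabolite"]
        weight = 1.0 / (1.0 + np.exp((mu - mu.mean()) / cfg.mu_sd))
        p_miss = cfg.metabolite_missing_rate * weight / weight.mean()
        p_miss = np.clip(p_miss, 0.0, 0.45)
        mask = streams["missing"].random(values["metabolite"].shape) < p_miss[:, None]
        values["metabolite"][mask] = np.nan

    matrices = {
        layer: OmicsMatrix(layer=layer, feature_ids=ids[layer], sample_ids=sample_ids, values=values[layer])
        for layer in layer_sizes
    }
    truth = TriomicsTruth(up=up, down=down, blocks=blocks)
    return matrices, meta, truth


# ---------------------------------------------------------------------------
# mito stress-test trace generator
# ---------------------------------------------------------------------------

def generate_mito_trace(
    basal_total: float,
    atp_frac: float,
    leak_frac: float,
    nonmito: float,
    max_fold: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_per_phase: int = 3,
    interval: float = 6.5,
):
    """Simulate a mito-stress-test OCR trace with known phase plateaus.

    ``atp_frac`` and ``leak_frac`` partition the mitochondrial part of the
    basal OCR (they must sum to 1); ``max_fold`` multiplies it after the
    uncoupler injection. Phase plateaus::

        baseline      basal_total
        post-oligo    nonmito + leak_frac * (basal_total - nonmito)
        post-FCCP     nonmito + max_fold * (basal_total - nonmito)
        post-Rot/AA   nonmito

    Gaussian noise of sd ``noise_sd`` is added to every measurement.
    """
    from .assays import MitoStressTrace

    if nonmito > basal_total:
        raise TriomixError("non-mitochondrial OCR cannot exceed the basal total")
    for name, frac in (("atp_frac", atp_frac), ("leak_frac", leak_frac)):
        if not 0 < frac < 1:
            raise TriomixError(f"{name} must be in (0, 1)")
    if abs(atp_frac + leak_frac - 1.0) > 1e-9:
        raise TriomixError("atp_frac + leak_frac must sum to 1 (they partition basal mito OCR)")
    if max_fold < 1:
        raise TriomixError("max_fold must be >= 1")
    mito = basal_total - nonmito
    plateaus = (
        basal_total,
        nonmito + leak_frac * mito,
        nonmito + max_fold * mito,
        nonmito,
    )
    rng = np.random.default_rng(seed)
    ocr = np.concatenate([
        level + rng.normal(0.0, noise_sd, size=n_per_phase) if noise_sd > 0 else np.full(n_per_phase, level)
        for level in plateaus
    ])
    time = np.arange(4 * n_per_phase) * interval
    return MitoStressTrace(
        time=time,
        ocr=ocr,
        oligomycin_idx=n_per_phase,
        fccp_idx=2 * n_per_phase,
        rotenone_idx=3 * n_per_phase,
    )
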