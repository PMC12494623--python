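"""Synthetic bead-array cohorts with planted, recorded ground truth.

Emulates a serum-autoantibody screening study end to end: an xMAP-style MFI
plate (samples x analytes with empty wells and control analytes), a clinical
table for the retained patients, and a STRING-style protein-interaction
graph.  Every planted effect is recorded in :class:`GroundTruth` so each
downstream analysis stage can be validated without any external data:

* three patient reactivity tiers (high / intermediate / low) entering the
  signal as antigen-specific multiplicative factors ``tier_scale ** w_j``
  with responsiveness weights ``w_j`` — reactivity differences are
  epitope-specific in magnitude, so tier structure survives between-sample
  normalization (a perfectly uniform scale factor would be removed by it);
* antigen-clinical rank correlations induced by a Gaussian copula on the
  tier-adjusted log reactivity (the antigen-specific component), solved
  exactly for multi-antigen targets against the realized rank scores;
* a high-tier-only clinical effect carried by a latent factor shared across
  a large antigen block (which doubles as the dominant co-reactive cluster);
* a sex mean-shift on a random antigen subset;
* antigens forced constant within the low tier (zero-variance planting);
* interaction-graph communities whose only strong inter-community routes
  run through planted bridge node(s), plus sub-threshold decoy edges.

Identical configurations (including the seed) produce byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import InteractionGraph
from .preprocess import RawPlate

TIER_NAMES = ("high", "intermediate", "low")

#: default clinical marginals: (mean, sd, lower clip, upper clip)
CLINICAL_NUMERIC = {
    "age": (70.97, 6.12, 40.0, 95.0),
    "IOP": (32.44, 5.58, 10.0, 60.0),
    "CCT": (541.40, 33.04, 400.0, 700.0),
    "SE": (0.5, 2.0, -10.0, 10.0),
    "VA": (0.7, 0.25, 0.0, 1.5),
    "MD": (-6.51, 4.89, -30.0, -0.01),
    "MD 3": (-10.07, 6.36, -30.0, -0.01),
    "VFI Diagnosis": (85.56, 14.40, 0.0, 100.0),
    "VFI 3": (74.92, 19.04, 0.0, 100.0),
    "ROP": (2.89, 2.43, 0.0, 15.0),
    "CD": (0.70, 0.15, 0.1, 1.0),
    "OCT": (70.0, 12.0, 30.0, 120.0),
    "medications": (2.70, 0.84, 0.0, 6.0),
}

#: P(level == "yes") for default binary parameters (sex handled separately)
CLINICAL_BINARY = {
    "diabetes": 0.15,
    "hypertension": 0.45,
    "migraine": 0.10,
    "smoking": 0.20,
    "SLT": 37 / 116,
    "GPA": 68 / 116,
}

_P_MALE = 56 / 116

CONTROL_ANALYTES = {
    "CTRL_HIS6ABP": "control_tag",
    "CTRL_BLANK": "control_blank",
    "CTRL_ANTI_IGG": "control_loading",
    "CTRL_EBNA1": "control_positive",
}


def antigen_ids(n: int) -> list:
    return [f"AG{j + 1:03d}" for j in range(n)]


@dataclass(frozen=True)
class GraphSpec:
    """Interaction-graph shape: dense communities joined only via bridges."""

    n_nodes: int = 60
    n_communities: int = 3
    p_within: float = 0.30
    n_bridges: int = 1
    bridge_attachment: float = 0.5
    strength_range: tuple = (0.2, 1.0)
    n_weak_edges: int = 40
    weak_range: tuple = (0.01, 0.15)


@dataclass(frozen=True)
class PlantedAssociation:
    """Target Spearman rho between one antigen and one clinical parameter,
    optionally restricted to a reactivity tier."""

    antigen: int
    parameter: str
    rho: float
    tier: str | None = None


@dataclass(frozen=True)
class PlantedBlockAssociation:
    """A latent factor shared by a block of antigens, coupled to a clinical
    parameter within one tier only (per-antigen rho approximately ``rho``)."""

    antigens: tuple
    parameter: str = "CCT"
    rho: float = -0.5
    tier: str = "high"
    factor_sd: float = 0.2



@dataclass(frozen=True)
class SimulationConfig:
    n_recruited: int = 125
    n_dropout: int = 9
    n_antigens: int = 92
    n_empty_wells: int = 4
    background_mean: float = 120.0
    background_sd: float = 10.0
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    signal_sigma: float = 0.3
    planted_signal_sigma: float = 0.45
    tech_sigma: float = 0.05
    tier_fractions: tuple = (35 / 116, 45 / 116, 36 / 116)
    tier_scale: tuple = (4.0, 2.0, 1.0)
    tier_responsiveness: tuple = (1.8, 2.8)
    responsive_fraction: float = 0.25
    planted_assoc: tuple = (
        PlantedAssociation(5, "SE", 0.3),
        PlantedAssociation(8, "SE", 0.3),
        PlantedAssociation(20, "SE", 0.3),
    )
    planted_block: PlantedBlockAssociation | None = PlantedBlockAssociation(
        antigens=tuple(range(46, 92))
    )
    # co-reactive blocks skip the planted-association antigens (5, 8, 20):
    # the planted rho stays a purely antigen-specific association instead of
    # spilling onto block-mates through a shared factor
    coreactive_blocks: tuple = (
        (tuple(j for j in range(0, 6) if j != 5), 0.35),
        (tuple(j for j in range(6, 16) if j != 8), 0.35),
        (tuple(j for j in range(16, 30) if j != 20), 0.35),
        (tuple(range(30, 46)), 0.35),
    )
    sex_effect_size: float = 1.5
    n_sex_antigens: int = 12
    low_tier_constant_antigens: tuple = tuple(range(86, 92))
    graph: GraphSpec = field(default_factory=GraphSpec)
    rng_seed: int = 0


@dataclass
class GroundTruth:
    true_background: float
    background_sd: float
    tier_of_patient: dict
    dropout_samples: tuple
    sex_of_patient: dict
    sex_shift_antigens: tuple
    sex_shifted_level: str
    planted: list
    planted_block: dict | None
    zero_variance_antigens: tuple
    coreactive_blocks: list
    bridge_nodes: tuple
    communities: list
    config: dict

    def to_payload(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    plate: RawPlate
    clinical: pd.DataFrame
    graph: InteractionGraph
    truth: GroundTruth

    def __post_init__(self):
        plate_samples = set(self.plate.sample_ids)
        clinical_ids = set(self.clinical.index)
        if not clinical_ids <= plate_samples:
            raise ValueError("clinical patients missing from the plate")
        n_extra = len(plate_samples - clinical_ids)
        if n_extra != len(self.truth.dropout_samples):
            raise ValueError("dropout bookkeeping inconsistent")


def validate_config(config: SimulationConfig) -> None:
    c = config
    for name in ("n_recruited", "n_antigens", "n_empty_wells"):
        if getattr(c, name) <= 0:
            raise ValueError(f"{name} must be positive")
    if not (0 <= c.n_dropout < c.n_recruited):
        raise ValueError("n_dropout must be in [0, n_recruited)")
    if abs(sum(c.tier_fractions) - 1.0) > 1e-9:
        raise ValueError("tier_fractions must sum to 1")
    if len(c.tier_scale) != 3 or len(c.tier_fractions) != 3:
        raise ValueError("exactly three tiers are modelled")
    if not (c.tier_scale[0] >= c.tier_scale[1] >= c.tier_scale[2] > 0):
        raise ValueError("tier_scale must be non-increasing high >= intermediate >= low")
    for pa in c.planted_assoc:
        if abs(pa.rho) >= 1:
            raise ValueError(f"planted rho {pa.rho} unreachable (|rho| >= 1)")
        if not (0 <= pa.antigen < c.n_antigens):
            raise ValueError(f"planted antigen index {pa.antigen} out of range")
        if pa.tier is not None and pa.tier not in TIER_NAMES:
            raise ValueError(f"unknown tier {pa.tier!r}")
    if c.planted_block is not None:
        if abs(c.planted_block.rho) >= 1:
            raise ValueError("planted block rho unreachable")
        if any(j < 0 or j >= c.n_antigens for j in c.planted_block.antigens):
            raise ValueError("planted block antigen index out of range")
    if any(j < 0 or j >= c.n_antigens for j in c.low_tier_constant_antigens):
        raise ValueError("low-tier constant antigen index out of range")
    if c.n_sex_antigens > c.n_antigens:
        raise ValueError("n_sex_antigens exceeds n_antigens")
    if c.graph.n_bridges >= c.graph.n_nodes:
        raise ValueError("n_bridges must be smaller than n_nodes")
    if c.graph.n_communities < 1:
        raise ValueError("need at least one community")


def _allocate(fractions, total: int) -> np.ndarray:
    """Largest-remainder integer allocation of ``total`` across fractions."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    remainder = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="mergesort")
    base[order[:remainder]] += 1
    return base


def _normal_scores(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, method="average")
    u = stats.norm.ppf((r - 0.5) / len(x))
    return (u - u.mean()) / u.std()


def _coupled_scores(U: np.ndarray, rho_targets, rng) -> np.ndarray:
    """Standard-normal scores with Pearson corr(score, U_j) = 2 sin(pi rho_j / 6)
    against each column of U — the Gaussian-copula latent that realizes the
    requested Spearman correlations after a monotone marginal transform."""
    n, k = U.shape
    R = np.corrcoef(U, rowvar=False) if k > 1 else np.array([[1.0]])
    R = np.atleast_2d(R)
    rstar = 2.0 * np.sin(np.pi * np.asarray(rho_targets, dtype=float) / 6.0)
    b = np.linalg.solve(R + 1e-10 * np.eye(k), rstar)
    s2 = float(b @ R @ b)
    if s2 >= 1.0:  # jointly infeasible targets: damp towards the boundary
        b *= math.sqrt(0.98 / s2)
        s2 = 0.98
    eps = rng.standard_normal(n)
    # project the noise out of span(U) so the realized correlation with each
    # antigen score equals the target exactly, not just in expectation
    coef, *_ = np.linalg.lstsq(U, eps, rcond=None)
    eps = eps - U @ coef
    eps = (eps - eps.mean()) / eps.std()
    score = U @ b + math.sqrt(1.0 - s2) * eps
    return (score - score.mean()) / score.std()


def _spearman(a, b) -> float:
    return float(stats.spearmanr(a, b)[0])


def simulate_bead_array(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset (plate + clinical + graph + truth)."""
    if config is None:
        config = SimulationConfig()
    validate_config(config)
    c = config
    rng = np.random.default_rng(c.rng_seed)
    n, m = c.n_recruited, c.n_antigens
    aids = antigen_ids(m)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    sigma = c.signal_sigma

    base = rng.normal(c.baseline_log_mean, c.baseline_log_sd, m)
    # sero-reactivity is sparse: only a fraction of antigens respond to the
    # patient's overall reactivity tier, with antigen-specific amplitude
    responsive = rng.random(m) < c.responsive_fraction
    w = np.where(
        responsive, rng.uniform(c.tier_responsiveness[0], c.tier_responsiveness[1], m), 0.0
    )
    # antigens carrying planted clinical correlations are tier-neutral so the
    # planted rho is a pure antigen-specific association, and their baseline
    # sits above assay background (the study's antigens were short-listed by
    # reactivity, so the associations of interest are measurable, not floored)
    for pa in c.planted_assoc:
        w[pa.antigen] = 0.0
        base[pa.antigen] = max(base[pa.antigen], c.baseline_log_mean + 0.5)

    dropout = np.sort(rng.choice(n, size=c.n_dropout, replace=False))
    retained = np.setdiff1d(np.arange(n), dropout)
    counts = _allocate(c.tier_fractions, len(retained))
    tier_codes = np.empty(n, dtype=int)
    tier_codes[retained] = rng.permutation(np.repeat(np.arange(3), counts))
    if len(dropout):
        tier_codes[dropout] = rng.choice(3, size=len(dropout), p=np.asarray(c.tier_fractions))

    sex_male = rng.random(n) < _P_MALE
    sex_antigens = np.sort(rng.choice(m, size=c.n_sex_antigens, replace=False))

    log_scale = np.log(np.asarray(c.tier_scale, dtype=float))
    tier_shift = np.outer(log_scale[tier_codes], w)  # (n, m): w_j * ln(scale_tier)
    L = base[None, :] + tier_shift

    block_truth = []
    for idxs, block_rho in c.coreactive_blocks:
        idxs = np.asarray(idxs, dtype=int)
        beta = sigma * math.sqrt(block_rho / (1.0 - block_rho))
        f = rng.standard_normal(n)
        L[:, idxs] += beta * f[:, None]
        block_truth.append({"antigens": [aids[j] for j in idxs], "latent_rho": block_rho})

    g = rng.standard_normal(n)
    if c.planted_block is not None:
        pb_idx = np.asarray(c.planted_block.antigens, dtype=int)
        beta_g = c.planted_block.factor_sd
        L[:, pb_idx] += beta_g * g[:, None]
        block_truth.append(
            {
                "antigens": [aids[j] for j in pb_idx],
                "latent_rho": beta_g**2 / (beta_g**2 + sigma**2),
                "carries": c.planted_block.parameter,
            }
        )

    shifted = ~sex_male  # shift applied to the female profiles
    L[np.ix_(shifted, sex_antigens)] += c.sex_effect_size * sigma

    # per-antigen reactivity spread: planted antigens carry the broad
    # inter-patient dynamic range typical of the reactive antigens a study
    # would shortlist, so their associations are measurable over assay noise
    col_sigma = np.full(m, sigma)
    for pa in c.planted_assoc:
        col_sigma[pa.antigen] = c.planted_signal_sigma
    L += rng.normal(0.0, 1.0, (n, m)) * col_sigma[None, :]
    # per-sample technical gain (serum handling / labelling efficiency):
    # the multiplicative sample-level bias that RSN is meant to remove
    tech = rng.normal(0.0, c.tech_sigma, n)
    L_measured = L + tech[:, None]
    signal = np.exp(L_measured)
    noise = rng.normal(c.background_mean, c.background_sd, (n, m))
    mfi = np.maximum(np.rint(signal + noise), 0.0)

    low_patients = np.flatnonzero(tier_codes == 2)
    zv_idx = np.asarray(c.low_tier_constant_antigens, dtype=int)
    if len(zv_idx) and len(low_patients):
        mfi[np.ix_(low_patients, zv_idx)] = 0.0

    # tier-free antigen reactivity: the clinical-coupling substrate (the
    # component of each antigen that between-sample normalization keeps)
    adjusted = L - tier_shift

    # ---- plate assembly (controls + empty wells) -------------------------
    ctrl = np.column_stack(
        [
            np.maximum(np.rint(rng.normal(3 * c.background_mean, c.background_sd, n)), 0.0),
            np.maximum(np.rint(rng.normal(c.background_mean, c.background_sd, n)), 0.0),
            np.maximum(np.rint(np.exp(rng.normal(8.0, 0.3, n))), 0.0),
            np.maximum(np.rint(np.exp(rng.normal(8.5, 0.4, n))), 0.0),
        ]
    )
    empty = np.maximum(
        np.rint(rng.normal(c.background_mean, c.background_sd, (c.n_empty_wells, m + 4))), 0.0
    )
    columns = aids + list(CONTROL_ANALYTES)
    plate_values = np.vstack([np.hstack([mfi, ctrl]), empty])
    empty_ids = [f"EMPTY{i + 1:02d}" for i in range(c.n_empty_wells)]
    plate_index = sample_ids + empty_ids
    plate = RawPlate(
        mfi=pd.DataFrame(plate_values, index=plate_index, columns=columns),
        well_role=pd.Series(
            ["sample"] * n + ["empty"] * c.n_empty_wells, index=plate_index, name="well_role"
        ),
        analyte_role=pd.Series(
            ["antigen"] * m + list(CONTROL_ANALYTES.values()), index=columns, name="analyte_role"
        ),
    )

    # ---- clinical table --------------------------------------------------
    ret_ids = [sample_ids[i] for i in retained]
    n_ret = len(retained)
    tier_ret = tier_codes[retained]
    scores = {p: rng.standard_normal(n_ret) for p in CLINICAL_NUMERIC}

    groups: dict = {}
    for pa in c.planted_assoc:
        groups.setdefault((pa.parameter, pa.tier), []).append(pa)
    planted_truth = []
    for (param, tier), items in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
    ):
        if tier is None:
            sub = np.arange(n_ret)
        else:
            sub = np.flatnonzero(tier_ret == TIER_NAMES.index(tier))
        global_idx = retained[sub]
        U = np.column_stack(
            [_normal_scores(adjusted[global_idx, pa.antigen]) for pa in items]
        )
        coupled = _coupled_scores(U, [pa.rho for pa in items], rng)
        scores[param][sub] = coupled
        for pa in items:
            planted_truth.append(
                {
                    "antigen": aids[pa.antigen],
                    "antigen_index": pa.antigen,
                    "parameter": param,
                    "tier": tier,
                    "target_rho": pa.rho,
                }
            )

    pb_truth = None
    if c.planted_block is not None:
        pb = c.planted_block
        sub = np.flatnonzero(tier_ret == TIER_NAMES.index(pb.tier))
        global_idx = retained[sub]
        g_sub = g[global_idx]
        g_std = (g_sub - g_sub.mean()) / g_sub.std()
        pb_idx = np.asarray(pb.antigens, dtype=int)
        corrs = [
            float(np.corrcoef(adjusted[global_idx, j], g_sub)[0, 1]) for j in pb_idx
        ]
        c_mean = float(np.mean(corrs))
        rstar = 2.0 * math.sin(math.pi * pb.rho / 6.0)
        a = np.clip(rstar / c_mean, -0.99, 0.99)
        coupled = a * g_std + math.sqrt(1.0 - a**2) * rng.standard_normal(len(sub))
        scores[pb.parameter][sub] = (coupled - coupled.mean()) / coupled.std()
        pb_truth = {
            "antigens": [aids[j] for j in pb_idx],
            "parameter": pb.parameter,
            "tier": pb.tier,
            "target_rho": pb.rho,
        }

    clinical = pd.DataFrame(index=pd.Index(ret_ids, name="patient_id"))
    for param, (mean, sd, lo, hi) in CLINICAL_NUMERIC.items():
        vals = np.clip(mean + sd * scores[param], lo, hi)
        if param == "medications":
            vals = np.maximum(np.rint(vals), 0.0)
        clinical[param] = vals
    clinical["sex"] = np.where(sex_male[retained], "male", "female")
    for param, p_yes in CLINICAL_BINARY.items():
        draws = rng.random(n_ret) < p_yes
        if param == "GPA":
            clinical[param] = np.where(draws, "progression", "stable")
        else:
            clinical[param] = np.where(draws, "yes", "no")

    # ---- realized correlations for the truth record ----------------------
    for rec in planted_truth:
        param, tier = rec["parameter"], rec["tier"]
        j = rec["antigen_index"]
        if tier is None:
            sub = np.arange(n_ret)
        else:
            sub = np.flatnonzero(tier_ret == TIER_NAMES.index(tier))
        global_idx = retained[sub]
        y = clinical[param].to_numpy()[sub]
        rec["realized_rho_coupled"] = _spearman(y, adjusted[global_idx, j])
        rec["realized_rho_raw"] = _spearman(y, mfi[global_idx, j])
    if pb_truth is not None:
        sub = np.flatnonzero(tier_ret == TIER_NAMES.index(pb_truth["tier"]))
        global_idx = retained[sub]
        y = clinical[pb_truth["parameter"]].to_numpy()[sub]
        raw_rhos = [
            _spearman(y, mfi[global_idx, j]) for j in np.asarray(c.planted_block.antigens)
        ]
        pb_truth["mean_realized_rho_raw"] = float(np.mean(raw_rhos))

    graph, graph_truth = simulate_interaction_graph(c)

    truth = GroundTruth(
        true_background=c.background_mean,
        background_sd=c.background_sd,
        tier_of_patient={sample_ids[i]: TIER_NAMES[tier_codes[i]] for i in range(n)},
        dropout_samples=tuple(sample_ids[i] for i in dropout),
        sex_of_patient={sample_ids[i]: ("male" if sex_male[i] else "female") for i in range(n)},
        sex_shift_antigens=tuple(aids[j] for j in sex_antigens),
        sex_shifted_level="female",
        planted=planted_truth,
        planted_block=pb_truth,
        zero_variance_antigens=tuple(aids[j] for j in zv_idx),
        coreactive_blocks=block_truth,
        bridge_nodes=tuple(graph_truth["bridges"]),
        communities=graph_truth["communities"],
        config=_config_payload(c),
    )
    return SyntheticDataset(plate=plate, clinical=clinical, graph=graph, truth=truth)


def _config_payload(config: SimulationConfig) -> dict:
    payload = asdict(config)
    payload["planted_assoc"] = [asdict(pa) for pa in config.planted_assoc]
    if config.planted_block is not None:
        payload["planted_block"] = asdict(config.planted_block)
    return payload


def simulate_interaction_graph(config: SimulationConfig):
    """Random community graph whose inter-community routes are forced
    through planted bridge node(s).

    Returns ``(InteractionGraph, graph_truth)`` where the graph keeps *all*
    edges (threshold 0), including sub-0.15 decoy edges between communities
    that a threshold filter must remove, and ``graph_truth`` records bridge
    identifiers and community memberships.
    """
    validate_config(config)
    gs = config.graph
    rng = np.random.default_rng(config.rng_seed + 1)
    n_members = gs.n_nodes - gs.n_bridges
    pool = antigen_ids(config.n_antigens)
    if n_members <= len(pool):
        members = list(rng.choice(pool, size=n_members, replace=False))
    else:
        members = pool + [f"NP{i + 1:03d}" for i in range(n_members - len(pool))]
        members = list(rng.permutation(members))
    sizes = _allocate([1 / gs.n_communities] * gs.n_communities, n_members)
    communities, pos = [], 0
    for s in sizes:
        communities.append(members[pos : pos + s])
        pos += s
    bridges = [f"BRP{i + 1:02d}" for i in range(gs.n_bridges)]

    G = nx.Graph()
    G.add_nodes_from(members + bridges)
    lo, hi = gs.strength_range

    def strong():
        return round(float(rng.uniform(lo, hi)), 3)

    for comm in communities:
        chain = list(rng.permutation(comm))
        for a, b in zip(chain, chain[1:]):  # spanning chain keeps it connected
            G.add_edge(a, b, strength=strong())
        for i in range(len(comm)):
            for j in range(i + 1, len(comm)):
                if not G.has_edge(comm[i], comm[j]) and rng.random() < gs.p_within:
                    G.add_edge(comm[i], comm[j], strength=strong())
    for bridge in bridges:
        for comm in communities:
            n_attach = max(1, math.ceil(gs.bridge_attachment * len(comm)))
            attach = rng.choice(comm, size=min(n_attach, len(comm)), replace=False)
            for node in attach:
                G.add_edge(bridge, str(node), strength=strong())
    # sub-threshold decoys between communities (would bypass the bridges)
    wlo, whi = gs.weak_range
    n_weak = 0
    attempts = 0
    while gs.n_communities > 1 and n_weak < gs.n_weak_edges and attempts < 20 * gs.n_weak_edges:
        attempts += 1
        ci, cj = rng.choice(gs.n_communities, size=2, replace=False)
        a = str(rng.choice(communities[ci]))
        b = str(rng.choice(communities[cj]))
        if not G.has_edge(a, b):
            G.add_edge(a, b, strength=round(float(rng.uniform(wlo, whi)), 3))
            n_weak += 1
    graph = InteractionGraph(graph=G, source="synthetic", dialect="fractional", threshold=0.0)
    return graph, {
        "bridges": bridges,
        "communities": [list(map(str, comm)) for comm in communities],
        "n_weak_edges": n_weak,
    }


def write_dataset(dataset: SyntheticDataset, directory, overwrite: bool = False) -> dict:
    """Emit plate.csv, clinical.csv, edges.tsv and truth.json; returns paths."""
    from pathlib import Path

    from . import io as sio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "plate": directory / "plate.csv",
        "clinical": directory / "clinical.csv",
        "edges": directory / "edges.tsv",
        "truth": directory / "truth.json",
    }
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite: {existing}")
    sio.write_plate(dataset.plate, paths["plate"])
    sio.write_clinical(dataset.clinical, paths["clinical"])
    sio.write_edges(dataset.graph, paths["edges"])
    sio.write_json(dataset.truth.to_payload(), paths["truth"])
    return paths


def read_dataset(directory):
    """Read back (plate, clinical, graph, truth-payload) from a directory."""
    from pathlib import Path

    from . import io as sio
    from .network import load_edges

    directory = Path(directory)
    plate = sio.read_plate(directory / "plate.csv")
    clinical = sio.read_clinical(directory / "clinical.csv")
    graph = load_edges(directory / "edges.tsv", threshold=0.0)
    truth = sio.read_json(directory / "truth.json")
    return plate, clinical, graph, truth
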