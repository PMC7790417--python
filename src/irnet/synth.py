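"""Synthetic iPSC cohort generator with planted ground truth.

Emulates the structure of a multi-clone iPSC expression study of insulin
resistance: ~100 donors with ~3 clones each, donor-level insulin status
(IR/IS by an SSPG threshold), technical (sequencing batch, RNA kit) and
biological (sex, age, BMI, ethnicity, reprogramming source cell) covariate
effects, block-correlated co-expression modules organised around planted
hub regulators ("key drivers"), cis-eQTL anchors on those regulators, and
an in-silico inhibition experiment whose effect attenuates geometrically
with directed distance from the target.

Generative model
----------------
Each gene ``g`` in sample ``s`` has a latent log2-scale signal

    z[g,s] = lam_g * F_m(donor) + sum_p w_pg * z[p,s] + beta_e * (dos - 2*maf)
             + noise_g,s

where ``F_m`` is a small per-module donor-level factor, the sum runs over
the gene's parents in the planted DAG (structural-equation propagation; this
is what makes the modules causally learnable rather than purely
factor-confounded) applying a mild quadratic perturb-response nonlinearity
``phi`` to each parent value (biochemical responses saturate and curve, and
this is what renders causal direction identifiable from observational
data), the eQTL term applies to anchor genes only, and the
noise has a donor-shared and a clone-specific component so clones of one
donor cluster together. Counts are negative binomial with gene-level
dispersion around library-scaled expected proportions of ``2**(baseline +
z + covariate effects + group effect)``; the IR-group effect is placed only
on genes strictly downstream of the planted key drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_prior_network",
    "simulate_perturbation",
    "simulate_gene_sets",
]

_DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "batch": 0.30,
    "rna_kit": 0.20,
    "source_cell": 0.20,
    "sex": 0.40,
    "age": 0.015,
    "bmi": 0.02,
    "ethnicity": 0.20,
}

# Loading of every module gene on its hub regulator's expression. The
# module "factor" is the planted key driver itself -- key drivers regulate
# their co-expression module -- so the factor is observed and conditioning
# on the hub blocks within-module confounding during network learning,
# while every module gene pair still shares ~ loading^2 of its variance
# whatever its distance in the planted tree (cohesive modules at the soft
# powers the scale-free criterion selects).
_HUB_LOADING = 0.6

# donor-level factor loading for hub genes themselves (and for modules
# without a planted driver, where the factor stays latent)
_FACTOR_LOADING = 0.25

# fraction of donor-level (vs clone-level) variance in the residual noise;
# clone-to-clone variability of iPSC lines is large (reprogramming
# stochasticity), so most residual noise is clone-specific, while the module
# factor and all genetic (eQTL) variance remain donor-level
_DONOR_NOISE_FRAC = 0.3

_MODULE_SET_NAMES = [
    "GO_GLUCOSE_METABOLIC_PROCESS",
    "GO_CHOLESTEROL_BIOSYNTHETIC_PROCESS",
    "GO_LIPID_METABOLIC_PROCESS",
    "GO_RESPIRATORY_ELECTRON_TRANSPORT_CHAIN",
    "GO_GLYCOLYTIC_PROCESS",
    "GO_HEXOSE_METABOLIC_PROCESS",
    "GO_STEROL_HOMEOSTASIS",
    "GO_MITOCHONDRION_ORGANIZATION",
]

_DECOY_SET_NAMES = [
    "GO_CILIUM_ASSEMBLY",
    "GO_SYNAPSE_ORGANIZATION",
    "GO_KERATINIZATION",
    "GO_DNA_REPAIR",
    "GO_RNA_SPLICING",
    "GO_AXON_GUIDANCE",
    "GO_IMMUNE_EFFECTOR_PROCESS",
    "GO_CELL_CYCLE_PHASE_TRANSITION",
]


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults emulate the study conditions.

    ``group_effect_size`` is in log2-fold-change units and is applied to
    IR-donor samples on key-driver-downstream genes only. ``covariate_effects``
    maps covariate name to the SD of its planted per-gene effect (log2 units;
    per-year / per-unit for age and BMI). ``attenuation`` multiplies the
    perturbation effect once per layer of directed distance from the target.
    """

    n_donors: int = 100
    clones_per_donor: int | tuple[int, int] = 3
    n_genes: int = 5000
    n_modules: int = 5
    module_size: tuple[int, int] = (30, 45)
    intra_module_corr: float = 0.6
    n_kd: int = 5
    kd_out_degree: tuple[int, int] = (11, 16)
    group_effect_size: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    sspg_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"IS": (84.0, 20.0), "IR": (210.0, 45.0)}
    )
    n_eqtl: int = 25
    eqtl_beta: float = 1.0
    perturb_target: str | None = None  # default: first planted key driver
    perturb_effect: float = 2.0
    attenuation: float = 0.5
    nonlinearity: float = 0.4
    dispersion: float = 0.04
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    is_fraction: float = 0.48
    decoy_frac: float = 0.2
    low_expr_frac: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1 or self.n_genes < 1 or self.n_modules < 1:
            raise ValueError("counts must be >= 1")
        if self.n_kd < 1 or self.n_kd > self.n_modules:
            raise ValueError("n_kd must be in 1..n_modules")
        lo, hi = self.module_size
        if lo < 2 or hi < lo:
            raise ValueError("invalid module_size range")
        if self.n_modules * hi > self.n_genes:
            raise ValueError("module sizes may exceed n_genes")
        if not 0 < self.intra_module_corr < 1:
            raise ValueError("intra_module_corr must be in (0,1)")
        if not 0 < self.attenuation < 1:
            raise ValueError("attenuation must be strictly in (0,1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def clone_counts(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if isinstance(self.clones_per_donor, (tuple, list)):
            lo, hi = self.clones_per_donor
            return rng.integers(lo, hi + 1, size=n)
        return np.full(n, int(self.clones_per_donor))


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated cohort."""

    module_assignment: dict[str, int]
    dag_edges: list[tuple[str, str]]
    edge_weights: dict[tuple[str, str], float]
    kd_set: list[str]
    de_truth: dict[str, float]
    covariate_truth: dict
    eqtl_genes: list[str]
    eqtl_markers: dict[str, str]
    perturb_target: str
    attenuation: float
    perturb_effect: float
    perturb_effects: dict[str, tuple[int, float]]
    dosages: pd.DataFrame
    gene_positions: pd.DataFrame
    marker_positions: pd.DataFrame
    generator_state: dict

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.module_assignment)
        g.add_edges_from(self.dag_edges)
        return g

    def skeleton(self) -> nx.Graph:
        return self.dag().to_undirected()

    def to_json(self) -> dict:
        """JSON-serializable view (generator internals and dosages omitted)."""
        return {
            "module_assignment": self.module_assignment,
            "dag_edges": [list(e) for e in self.dag_edges],
            "kd_set": list(self.kd_set),
            "de_truth": self.de_truth,
            "covariate_truth": self.covariate_truth,
            "eqtl_genes": list(self.eqtl_genes),
            "eqtl_markers": self.eqtl_markers,
            "perturb_target": self.perturb_target,
            "attenuation": self.attenuation,
            "perturb_effect": self.perturb_effect,
            "perturb_effects": {g: list(v) for g, v in self.perturb_effects.items()},
        }


def _response(x: np.ndarray, c: float) -> np.ndarray:
    """Mild quadratic perturb-response curve, unit variance for N(0,1) input.

    ``c = 0`` is purely linear; the quadratic component models the curvature
    of biochemical dose-response relations and makes the causal direction of
    an edge identifiable by additive-noise reasoning.
    """
    if c == 0:
        return x
    xq = np.clip(x, -3.0, 3.0)  # saturate so chained responses stay bounded
    return (x + c * (xq * xq - 1.0) / np.sqrt(2.0)) / np.sqrt(1.0 + c * c)


# --------------------------------------------------------------------------
# DAG construction
# --------------------------------------------------------------------------


def _build_module_dag(
    kd: str,
    descendants: Sequence[str],
    out_degree: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], list[list[str]]]:
    """Layered hub subtree: KD -> layer1 -> layer2 -> ... (geometric widths).

    Every layer-k node draws its parent(s) from layer k-1 only, so the
    planted layer equals the shortest directed distance from the hub.
    """
    total = len(descendants)
    lo, hi = out_degree
    l1 = int(rng.integers(lo, hi + 1))
    l1 = min(l1, total)
    sizes = [l1]
    rem = total - l1
    width = l1
    while rem > 0 and len(sizes) < 5:  # geometric widths, depth capped at 6
        width = max(1, int(round(width * 0.7)))
        take = min(width, rem)
        sizes.append(take)
        rem -= take
    if rem > 0:
        sizes.append(rem)
    layers: list[list[str]] = []
    idx = 0
    for size in sizes:
        layers.append(list(descendants[idx : idx + size]))
        idx += size
    edges: list[tuple[str, str]] = [(kd, child) for child in layers[0]]
    for k in range(1, len(layers)):
        prev = layers[k - 1]
        for node in layers[k]:
            parent = prev[int(rng.integers(len(prev)))]
            edges.append((parent, node))
            if len(prev) > 1 and rng.random() < 0.3:
                second = parent
                while second == parent:
                    second = prev[int(rng.integers(len(prev)))]
                edges.append((second, node))
    return edges, layers


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


def simulate_cohort(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (counts, sample metadata, planted truth) for one cohort.

    Returns raw integer counts (genes x samples), a metadata table with one
    row per sample (sample_id, donor_id, sspg, group, sex, age, bmi,
    ethnicity, batch, rna_kit, source_cell) and the :class:`SyntheticTruth`.
    """
    params.validate()
    rng = substream(params.seed, "cohort")

    # ----- donors and samples -------------------------------------------
    n_don = params.n_donors
    donor_ids = [f"D{i + 1:03d}" for i in range(n_don)]
    n_is = int(round(params.is_fraction * n_don))
    order = rng.permutation(n_don)
    group = np.array(["IR"] * n_don, dtype=object)
    group[order[:n_is]] = "IS"
    sspg = np.empty(n_don)
    for lab in ("IS", "IR"):
        mu, sd = params.sspg_params[lab]
        mask = group == lab
        sspg[mask] = np.clip(rng.normal(mu, sd, mask.sum()), 1.0, None)
    sex = rng.choice(["F", "M"], size=n_don)
    age = np.clip(rng.normal(58, 8, n_don), 25, 80).round(1)
    bmi = np.clip(rng.normal(29, 4, n_don), 18, 45).round(1)
    ethnicity = rng.choice(["eur", "his", "asi"], size=n_don, p=[0.6, 0.25, 0.15])
    source_cell = rng.choice(["fibroblast", "blood"], size=n_don, p=[0.7, 0.3])

    clones = params.clone_counts(rng, n_don)
    sample_ids: list[str] = []
    donor_of: list[int] = []
    for d in range(n_don):
        for c in range(int(clones[d])):
            sample_ids.append(f"{donor_ids[d]}_c{c + 1}")
            donor_of.append(d)
    donor_idx = np.asarray(donor_of)
    n_smp = len(sample_ids)
    batch = rng.choice([f"b{i}" for i in range(1, 5)], size=n_smp)
    rna_kit = rng.choice(["kitA", "kitB"], size=n_smp)

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": [donor_ids[d] for d in donor_idx],
            "sspg": sspg[donor_idx].round(1),
            "group": group[donor_idx],
            "sex": sex[donor_idx],
            "age": age[donor_idx],
            "bmi": bmi[donor_idx],
            "ethnicity": ethnicity[donor_idx],
            "batch": batch,
            "rna_kit": rna_kit,
            "source_cell": source_cell[donor_idx],
        }
    )

    # ----- gene partition: modules (hub subtrees), decoys, background ----
    n_genes = params.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sizes = rng.integers(params.module_size[0], params.module_size[1] + 1,
                         size=params.n_modules)
    if int(sizes.sum()) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    shuffled = [gene_ids[i] for i in rng.permutation(n_genes)]
    pos = 0
    module_assignment: dict[str, int] = {g: 0 for g in gene_ids}
    module_nodes: list[list[str]] = []
    for m in range(params.n_modules):
        nodes = shuffled[pos : pos + int(sizes[m])]
        pos += int(sizes[m])
        for g in nodes:
            module_assignment[g] = m + 1
        module_nodes.append(nodes)
    n_decoy = min(int(round(params.decoy_frac * n_genes)), n_genes - pos)
    decoys = shuffled[pos : pos + n_decoy]
    pos += n_decoy
    background = shuffled[pos:]

    # ----- planted DAG ---------------------------------------------------
    kd_set: list[str] = []
    dag_edges: list[tuple[str, str]] = []
    edge_weights: dict[tuple[str, str], float] = {}
    targets: list[str] = []
    sqrt_p = np.sqrt(params.intra_module_corr)
    w_lo, w_hi = 0.97 * sqrt_p, min(0.95, 1.16 * sqrt_p)
    for m in range(params.n_modules):
        nodes = module_nodes[m]
        kd = nodes[0]
        if m < params.n_kd:
            kd_set.append(kd)
        edges, _layers = _build_module_dag(kd, nodes[1:], params.kd_out_degree, rng)
        for u, v in edges:
            dag_edges.append((u, v))
            edge_weights[(u, v)] = float(rng.uniform(w_lo, w_hi))
        targets.extend(nodes[1:])
    # decoy regulators: exogenous genes with a few edges into random targets
    for g in decoys:
        n_child = int(rng.integers(1, 4))
        children = rng.choice(targets, size=min(n_child, len(targets)), replace=False)
        for child in children:
            dag_edges.append((g, str(child)))
            edge_weights[(g, str(child))] = float(rng.uniform(0.3, 0.5))

    dag = nx.DiGraph(dag_edges)
    if not nx.is_directed_acyclic_graph(dag):  # pragma: no cover - by construction
        raise AssertionError("planted DAG must be acyclic")

    # downstream-of-KD genes carry the IR group effect
    kd_downstream: set[str] = set()
    for kd in kd_set:
        kd_downstream |= nx.descendants(dag, kd)
    de_sign = {g: float(rng.choice([-1.0, 1.0])) for g in sorted(kd_downstream)}
    de_truth = {g: s * params.group_effect_size for g, s in de_sign.items()}

    # ----- cis-eQTL anchors ----------------------------------------------
    exogenous = [g for g in decoys + background]
    n_extra = max(0, params.n_eqtl - len(kd_set))
    extra = [str(g) for g in rng.choice(exogenous, size=min(n_extra, len(exogenous)),
                                        replace=False)]
    eqtl_genes = kd_set[: params.n_eqtl] + extra
    gene_tss = {g: 200_000 * (i + 1) for i, g in enumerate(gene_ids)}
    marker_ids = [f"M{i + 1:05d}" for i in range(n_genes)]
    marker_pos = {
        marker_ids[i]: int(gene_tss[gene_ids[i]] + rng.integers(-900_000, 900_001))
        for i in range(n_genes)
    }
    marker_pos = {m: max(1, p) for m, p in marker_pos.items()}
    eqtl_markers = {g: marker_ids[gene_ids.index(g)] for g in eqtl_genes}
    maf = rng.uniform(0.2, 0.5, size=n_genes)
    dosages = rng.binomial(2, maf[None, :], size=(n_don, n_genes)).astype(float)
    dosages_df = pd.DataFrame(dosages, index=donor_ids, columns=marker_ids)

    # ----- latent signal -------------------------------------------------
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    parents_of: dict[str, list[tuple[str, float]]] = {g: [] for g in gene_ids}
    for (u, v), w in edge_weights.items():
        parents_of[v].append((u, w))
    kd_of_module = {m + 1: module_nodes[m][0] for m in range(params.n_kd)}
    lam = np.zeros(n_genes)
    for m, nodes in enumerate(module_nodes):
        hub = kd_of_module.get(m + 1)
        for g in nodes:
            if hub is None or g == hub:
                lam[gene_index[g]] = _FACTOR_LOADING
            else:
                lam[gene_index[g]] = _HUB_LOADING
    scaled_parents: dict[str, list[tuple[str, float]]] = {}
    for g in gene_ids:
        plist = parents_of[g]
        w2 = sum(w * w for _, w in plist)
        if w2 > 0.8:
            scale = np.sqrt(0.8 / w2)
            plist = [(p, w * scale) for p, w in plist]
        scaled_parents[g] = plist

    factor = rng.normal(size=(params.n_modules, n_don))
    e_don = rng.normal(size=(n_genes, n_don))
    e_cln = rng.normal(size=(n_genes, n_smp))
    unit_noise = (
        np.sqrt(_DONOR_NOISE_FRAC) * e_don[:, donor_idx]
        + np.sqrt(1 - _DONOR_NOISE_FRAC) * e_cln
    )

    # Noise per gene is calibrated on the fly so a child's parent-signal
    # fraction equals intra_module_corr: siblings then share ~rho of their
    # variance while a child keeps ~sqrt(rho) correlation with its parent,
    # whatever inflation chaining, the eQTL term or the response curve cause.
    # Each child is then rescaled to unit latent variance so variance does
    # not grow multiplicatively down regulatory chains.
    z = np.zeros((n_genes, n_smp))
    noise_sd = np.empty(n_genes)
    z_gain = np.ones(n_genes)
    rho = params.intra_module_corr
    topo = list(nx.topological_sort(dag))
    topo_all = topo + [g for g in gene_ids if g not in dag]
    for g in topo_all:
        gi = gene_index[g]
        signal = np.zeros(n_smp)
        mod = module_assignment[g]
        if mod > 0:
            hub = kd_of_module.get(mod)
            if hub is None or g == hub:
                signal = signal + lam[gi] * factor[mod - 1, donor_idx]
            else:
                signal = signal + lam[gi] * _response(
                    z[gene_index[hub]], params.nonlinearity)
        for p, w in scaled_parents[g]:
            signal = signal + w * _response(z[gene_index[p]], params.nonlinearity)
        if g in eqtl_markers:
            dos = dosages[:, gene_index[g]]
            signal = signal + params.eqtl_beta * (dos - dos.mean())[donor_idx]
        if scaled_parents[g]:
            sig_var = max(float(signal.var()), 1e-6)
            noise_sd[gi] = np.sqrt(sig_var * (1.0 - rho) / rho)
            z_gain[gi] = np.sqrt(rho / sig_var)
        else:
            noise_sd[gi] = np.sqrt(max(0.3, 1.0 - lam[gi] ** 2))
        z[gi] = z_gain[gi] * (signal + noise_sd[gi] * unit_noise[gi])

    # ----- covariate effects --------------------------------------------
    covariate_truth: dict[str, dict] = {}
    cov_shift = np.zeros((n_genes, n_smp))
    cov_values = {
        "batch": batch,
        "rna_kit": rna_kit,
        "source_cell": source_cell[donor_idx],
        "sex": sex[donor_idx],
        "ethnicity": ethnicity[donor_idx],
        "age": age[donor_idx],
        "bmi": bmi[donor_idx],
    }
    for cov, mag in params.covariate_effects.items():
        if cov not in cov_values or mag == 0:
            continue
        vals = cov_values[cov]
        affected = rng.random(n_genes) < 0.3
        if cov in ("age", "bmi"):
            slopes = rng.normal(0.0, mag, size=n_genes) * affected
            centered = np.asarray(vals, dtype=float) - float(np.mean(vals))
            cov_shift += slopes[:, None] * centered[None, :]
            covariate_truth[cov] = {
                gene_ids[i]: float(slopes[i]) for i in np.where(affected)[0]
            }
        else:
            levels = sorted(set(map(str, vals)))
            offs = rng.normal(0.0, mag, size=(n_genes, len(levels)))
            offs -= offs.mean(axis=1, keepdims=True)
            offs *= affected[:, None]
            level_idx = np.array([levels.index(str(v)) for v in vals])
            cov_shift += offs[:, level_idx]
            covariate_truth[cov] = {
                gene_ids[i]: {lev: float(offs[i, j]) for j, lev in enumerate(levels)}
                for i in np.where(affected)[0]
            }

    # ----- group effect --------------------------------------------------
    ir_samples = (group[donor_idx] == "IR").astype(float)
    delta = np.zeros(n_genes)
    for g, d in de_truth.items():
        delta[gene_index[g]] = d
    group_shift = delta[:, None] * ir_samples[None, :]

    # ----- counts --------------------------------------------------------
    baseline = rng.uniform(4.5, 9.0, size=n_genes)
    n_low = int(round(params.low_expr_frac * n_genes))
    if n_low and background:
        low = rng.choice(background, size=min(n_low, len(background)), replace=False)
        for g in low:
            baseline[gene_index[str(g)]] = rng.uniform(-2.0, 1.0)
    log2_mu = baseline[:, None] + z + cov_shift + group_shift
    rel = np.exp2(log2_mu)
    rel /= rel.sum(axis=0, keepdims=True)
    lib = rng.uniform(*params.lib_size_range, size=n_smp)
    mu = rel * lib[None, :]
    phi = params.dispersion * np.exp(rng.normal(0.0, 0.25, size=n_genes))
    size_nb = 1.0 / phi
    p_nb = size_nb[:, None] / (size_nb[:, None] + mu)
    counts = rng.negative_binomial(size_nb[:, None], p_nb)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    # ----- perturbation schedule ----------------------------------------
    perturb_target = params.perturb_target or kd_set[0]
    perturb_effects = _perturbation_schedule(
        dag, perturb_target, params.perturb_effect, params.attenuation
    )

    truth = SyntheticTruth(
        module_assignment=module_assignment,
        dag_edges=dag_edges,
        edge_weights=edge_weights,
        kd_set=kd_set,
        de_truth=de_truth,
        covariate_truth=covariate_truth,
        eqtl_genes=eqtl_genes,
        eqtl_markers=eqtl_markers,
        perturb_target=perturb_target,
        attenuation=params.attenuation,
        perturb_effect=params.perturb_effect,
        perturb_effects=perturb_effects,
        dosages=dosages_df,
        gene_positions=pd.DataFrame(
            {"gene": gene_ids, "tss": [gene_tss[g] for g in gene_ids]}
        ),
        marker_positions=pd.DataFrame(
            {"marker": marker_ids, "pos": [marker_pos[m] for m in marker_ids]}
        ),
        generator_state={
            "gene_ids": gene_ids,
            "baseline": baseline,
            "noise_sd": noise_sd,
            "z_gain": z_gain,
            "lam": lam,
            "kd_of_module": kd_of_module,
            "scaled_parents": scaled_parents,
            "phi": phi,
            "topo_all": topo_all,
        },
    )
    _check_truth_invariants(truth, params)
    return counts_df, metadata, truth


def _perturbation_schedule(
    dag: nx.DiGraph, target: str, effect: float, attenuation: float
) -> dict[str, tuple[int, float]]:
    if target not in dag:
        raise ValueError(f"unknown perturbation target {target!r}")
    dist = nx.single_source_shortest_path_length(dag, target)
    out: dict[str, tuple[int, float]] = {}
    for g, layer in dist.items():
        if layer == 0:
            continue
        out[g] = (layer, -effect * attenuation ** (layer - 1))
    return out


def _check_truth_invariants(truth: SyntheticTruth, params: SimulationParams) -> None:
    dag = truth.dag()
    assert nx.is_directed_acyclic_graph(dag)
    lo, hi = params.kd_out_degree
    for kd in truth.kd_set:
        deg = dag.out_degree(kd)
        if not lo <= deg <= hi:
            # out-degree can only be clipped downward when a module is tiny
            assert deg <= hi


# --------------------------------------------------------------------------
# prior network
# --------------------------------------------------------------------------


def simulate_prior_network(
    truth: SyntheticTruth,
    extra_edge_frac: float = 0.25,
    removal_frac: float = 0.05,
    seed: int = 0,
) -> nx.Graph:
    """Noisy undirected prior: the truth skeleton with a stated fraction of
    random extra edges added and of true edges removed.

    Prior interaction databases mix directed and undirected evidence with no
    trusted direction, so the prior is returned undirected.
    """
    rng = substream(seed, "prior")
    skeleton = truth.skeleton()
    genes = sorted(truth.module_assignment)
    edges = sorted(tuple(sorted(e)) for e in skeleton.edges())
    n_true = len(edges)
    n_remove = int(round(removal_frac * n_true))
    if n_remove:
        drop = set(map(int, rng.choice(n_true, size=n_remove, replace=False)))
        edges = [e for i, e in enumerate(edges) if i not in drop]
    existing = set(edges)
    n_extra = int(round((1.0 + extra_edge_frac) * n_true)) - n_true
    added = 0
    while added < n_extra:
        u, v = rng.choice(len(genes), size=2, replace=False)
        e = tuple(sorted((genes[int(u)], genes[int(v)])))
        if e not in existing:
            existing.add(e)
            edges.append(e)
            added += 1
    prior = nx.Graph()
    prior.add_nodes_from(genes)
    prior.add_edges_from(edges)
    return prior


# --------------------------------------------------------------------------
# in-silico perturbation
# --------------------------------------------------------------------------


def simulate_perturbation(
    params: SimulationParams,
    truth: SyntheticTruth,
    target: str | None = None,
    n_per_arm: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired treated/control count matrices for an in-silico inhibition.

    Treated samples shift each gene downstream of ``target`` by
    ``-perturb_effect * attenuation**(layer-1)`` log2 units, where layer is
    the shortest directed distance from the target in the planted DAG;
    unreachable genes are unshifted. Arms are paired: sample ``T_i`` shares
    its latent state with ``C_i`` (same line with and without inhibitor).
    """
    target = target or truth.perturb_target
    dag = truth.dag()
    if target not in dag:
        raise ValueError(f"unknown perturbation target {target!r}")
    schedule = _perturbation_schedule(dag, target, params.perturb_effect,
                                      params.attenuation)
    rng = substream(seed, f"perturb:{target}")
    state = truth.generator_state
    gene_ids: list[str] = state["gene_ids"]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    factor = rng.normal(size=(params.n_modules, n_per_arm))
    noise = rng.normal(size=(n_genes, n_per_arm))
    z = np.zeros((n_genes, n_per_arm))
    lam = state["lam"]
    noise_sd = state["noise_sd"]
    gain = state["z_gain"]
    kd_of_module = state["kd_of_module"]
    for g in state["topo_all"]:
        gi = gene_index[g]
        row = noise_sd[gi] * noise[gi]
        mod = truth.module_assignment[g]
        if mod > 0:
            hub = kd_of_module.get(mod)
            if hub is None or g == hub:
                row = row + lam[gi] * factor[mod - 1]
            else:
                row = row + lam[gi] * _response(z[gene_index[hub]],
                                                params.nonlinearity)
        for p, w in state["scaled_parents"][g]:
            row = row + w * _response(z[gene_index[p]], params.nonlinearity)
        z[gi] = gain[gi] * row

    shift = np.zeros(n_genes)
    for g, (_layer, s) in schedule.items():
        shift[gene_index[g]] = s

    def _draw(zmat: np.ndarray, prefix: str) -> pd.DataFrame:
        log2_mu = state["baseline"][:, None] + zmat
        rel = np.exp2(log2_mu)
        rel /= rel.sum(axis=0, keepdims=True)
        lib = rng.uniform(*params.lib_size_range, size=n_per_arm)
        mu = rel * lib[None, :]
        size_nb = 1.0 / state["phi"]
        p_nb = size_nb[:, None] / (size_nb[:, None] + mu)
        counts = rng.negative_binomial(size_nb[:, None], p_nb)
        cols = [f"{prefix}{i + 1:02d}" for i in range(n_per_arm)]
        return pd.DataFrame(counts, index=gene_ids, columns=cols)

    treated = _draw(z + shift[:, None], "T")
    control = _draw(z, "C")
    return treated, control


# --------------------------------------------------------------------------
# gene sets
# --------------------------------------------------------------------------


def simulate_gene_sets(
    truth: SyntheticTruth,
    seed: int = 0,
    drop_frac: float = 0.1,
    add_frac: float = 0.05,
    n_decoy_sets: int = 8,
) -> dict[str, set[str]]:
    """GMT-style gene sets: metabolic-named sets tracking the planted modules
    (with some membership noise) plus irrelevant decoy sets."""
    rng = substream(seed, "gene_sets")
    genes = sorted(truth.module_assignment)
    by_module: dict[int, list[str]] = {}
    for g, m in truth.module_assignment.items():
        if m > 0:
            by_module.setdefault(m, []).append(g)
    gene_sets: dict[str, set[str]] = {}
    for m in sorted(by_module):
        name = _MODULE_SET_NAMES[(m - 1) % len(_MODULE_SET_NAMES)]
        if m - 1 >= len(_MODULE_SET_NAMES):
            name = f"{name}_{m}"
        members = sorted(by_module[m])
        keep = [g for g in members if rng.random() >= drop_frac]
        n_add = int(round(add_frac * len(members)))
        extras = rng.choice(genes, size=n_add, replace=False)
        gene_sets[name] = set(keep) | set(map(str, extras))
    unassigned = [g for g, m in truth.module_assignment.items() if m == 0]
    for i in range(n_decoy_sets):
        name = _DECOY_SET_NAMES[i % len(_DECOY_SET_NAMES)]
        size = int(rng.integers(30, 80))
        members = rng.choice(unassigned, size=min(size, len(unassigned)),
                             replace=False)
        gene_sets[name] = set(map(str, members))
    return gene_sets
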