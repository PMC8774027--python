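"""Synthetic multi-study bulk transcriptomes with known cell composition.

This module generates everything the downstream stages consume, with the
ground truth exported alongside: a linear-scale cell-type reference with
planted marker genes, multi-study case/control bulk mixtures whose
cell-type proportions shift with disease status (neurons down,
oligodendrocytes and endothelial cells up, as observed in degenerating
substantia nigra), study-level batch effects, sex effects on a small set
of Y-linked-like genes, a planted set of genuinely condition-responsive
genes, and toy protein-interaction graphs with planted hubs.

The generative model for a bulk sample i and gene g is

    y_ig = log2( sum_k p_ik * R_kg ) + b_{study(i),g} + s_g * d * case_i
           + h * male_i * [g is sex gene] + e_ig

where ``p_i`` is a Dirichlet-distributed proportion vector (case and
control groups use different Dirichlet parameters), ``R`` is the
linear-scale reference, ``b`` is a per-study per-gene batch offset,
``d`` the planted log2 effect with sign ``s_g`` for true DEGs, and ``e``
i.i.d. Gaussian noise.  Mixing happens on the linear scale; batch,
condition, sex, and noise effects are additive on the log2 scale,
matching the microarray convention of log-additive effects on linear
mixtures.

Default cohort structure mirrors a nine-study substantia nigra
case/control compendium: 70 control and 88 case samples in the study
group sizes of that compendium, six cell types, and Dirichlet parameters
chosen so the neuronal proportion drops by about one pooled standard
deviation in cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream, subseed

__all__ = [
    "SimulationConfig",
    "ReferencePanel",
    "ExpressionSet",
    "GroundTruth",
    "simulate_reference",
    "simulate_bulk",
    "simulate_ppi",
    "DEFAULT_CELL_TYPES",
]

#: Cell types of the default six-type brain reference, in a fixed order:
#: neurons, oligodendrocytes, astrocytes, microglia, oligodendrocyte
#: precursors, endothelial cells.
DEFAULT_CELL_TYPES = ("NEU", "ODC", "AST", "MIC", "OPC", "END")

# Per-study (control, case) group sizes of the emulated nine-study cohort.
_DEFAULT_GROUPS = ((9, 16), (7, 9), (6, 6), (15, 11), (9, 8), (5, 6), (8, 15), (5, 8), (6, 9))

# Dirichlet parameters (concentration 30.3 in both groups).  Control
# means (.396, .297, .158, .059, .050, .040); cases shift neurons down
# and oligodendrocytes up by about one pooled SD each.  The status
# shift is deliberately confined to the NEU/ODC subspace -- the two
# cell types the composition-aware model uses as covariates -- so that
# correcting for them can in principle remove all composition-driven
# differential expression; the other four types vary across samples
# but not with status.
_ALPHA_CONTROL = (12.0, 9.0, 4.8, 1.8, 1.5, 1.2)
_ALPHA_CASE = (9.3, 11.7, 4.8, 1.8, 1.5, 1.2)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; one integer seed fixes everything.

    Counts must be >= 1, standard deviations >= 0, Dirichlet parameters
    > 0.  ``n_per_group`` holds one (control, case) pair per study.
    """

    n_studies: int = 9
    n_per_group: tuple[tuple[int, int], ...] = _DEFAULT_GROUPS
    n_genes: int = 2000
    n_celltypes: int = 6
    dirichlet_alpha_control: tuple[float, ...] = _ALPHA_CONTROL
    dirichlet_alpha_case: tuple[float, ...] = _ALPHA_CASE
    study_sd: float = 0.3
    noise_sd: float = 0.5
    n_true_degs: int = 30
    deg_effect: float = 1.0
    n_markers_per_type: int = 20
    marker_lfc: float = 3.0
    celltype_sd: float = 2.0
    gender_gene_count: int = 8
    gender_effect: float = 2.0
    base_mean: float = 7.0
    base_sd: float = 1.0
    male_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_studies": self.n_studies,
            "n_genes": self.n_genes,
            "n_celltypes": self.n_celltypes,
            "n_true_degs": self.n_true_degs,
            "n_markers_per_type": self.n_markers_per_type,
            "gender_gene_count": self.gender_gene_count,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if len(self.n_per_group) != self.n_studies:
            raise ValueError("n_per_group must have one (control, case) pair per study")
        for sd_name in ("study_sd", "noise_sd", "base_sd", "celltype_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        for alpha in (self.dirichlet_alpha_control, self.dirichlet_alpha_case):
            if len(alpha) != self.n_celltypes:
                raise ValueError("Dirichlet parameter length must equal n_celltypes")
            if any(a <= 0 for a in alpha):
                raise ValueError("Dirichlet parameters must be > 0")
        if self.n_markers_per_type * self.n_celltypes > self.n_genes:
            raise ValueError(
                "n_markers_per_type * n_celltypes exceeds n_genes; "
                "not enough genes to assign disjoint marker panels"
            )

    @property
    def cell_types(self) -> tuple[str, ...]:
        if self.n_celltypes == len(DEFAULT_CELL_TYPES):
            return DEFAULT_CELL_TYPES
        return tuple(f"CT{i + 1}" for i in range(self.n_celltypes))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_genes))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_genes))

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_studies))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "n_per_group" in d:
            d["n_per_group"] = tuple(tuple(int(x) for x in pair) for pair in d["n_per_group"])
        for key in ("dirichlet_alpha_control", "dirichlet_alpha_case"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)


@dataclass
class ReferencePanel:
    """Linear-scale reference (cell types x genes) plus its marker map."""

    signatures: pd.DataFrame
    marker_map: dict[str, list[str]]


@dataclass
class ExpressionSet:
    """A bulk log2 expression matrix (genes x samples) with metadata.

    ``meta`` is indexed by sample id with columns ``study``, ``status``
    (control/case), ``gender`` (F/M), ``age``, ``braak``.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    true_proportions: pd.DataFrame
    deg_effects: dict[str, float]
    marker_map: dict[str, list[str]]
    gender_labels: pd.Series
    gender_genes: list[str]
    gender_effect: float

    @property
    def true_deg_ids(self) -> list[str]:
        return list(self.deg_effects)

    def to_dict(self) -> dict:
        return {
            "true_proportions": {
                s: self.true_proportions.loc[s].to_dict() for s in self.true_proportions.index
            },
            "deg_effects": self.deg_effects,
            "marker_map": self.marker_map,
            "gender_labels": self.gender_labels.to_dict(),
            "gender_genes": self.gender_genes,
            "gender_effect": self.gender_effect,
        }


def simulate_reference(config: SimulationConfig) -> ReferencePanel:
    """Draw a linear-scale cell-type signature matrix with planted markers.

    Non-marker genes get a log-normal baseline shared across types,
    modulated per type by a log2-normal factor with spread
    ``celltype_sd`` (so a realistic fraction of genes is strongly
    type-biased).  Each marker gene's value in its own type exceeds its
    maximum over all other types by at least ``marker_lfc`` log2 units.
    """
    rng = substream(config.seed, "reference")
    genes = np.array(config.gene_ids)
    types = list(config.cell_types)
    k, g = config.n_celltypes, config.n_genes

    baseline = 2.0 ** rng.normal(config.base_mean, config.base_sd, size=g)
    type_factor = 2.0 ** rng.normal(0.0, config.celltype_sd, size=(k, g))
    ref = baseline[None, :] * type_factor

    marker_idx = rng.choice(g, size=config.n_markers_per_type * k, replace=False)
    marker_map: dict[str, list[str]] = {}
    for t_i, t in enumerate(types):
        idx = marker_idx[t_i * config.n_markers_per_type : (t_i + 1) * config.n_markers_per_type]
        marker_map[t] = [str(x) for x in genes[idx]]
        # markers: dim in every other type, bright in their own
        off = baseline[idx] * 2.0 ** rng.normal(0.0, 0.3, size=(k, idx.size))
        ref[:, idx] = off
        headroom = config.marker_lfc + rng.uniform(0.2, 1.0, size=idx.size)
        others = np.delete(np.arange(k), t_i)
        ref[t_i, idx] = ref[np.ix_(others, idx)].max(axis=0) * 2.0**headroom

    signatures = pd.DataFrame(ref, index=types, columns=genes)
    return ReferencePanel(signatures=signatures, marker_map=marker_map)


def _pick_disjoint(rng: np.random.Generator, pool: np.ndarray, n: int) -> np.ndarray:
    if n > pool.size:
        raise ValueError("not enough genes left to assign without overlap")
    return rng.choice(pool, size=n, replace=False)


def simulate_bulk(config: SimulationConfig, reference: ReferencePanel) -> tuple[ExpressionSet, GroundTruth]:
    """Mix the reference into multi-study bulk samples with planted effects.

    Per-study random substreams are derived from the global seed by fixed
    keys, so adding a study never perturbs earlier studies.
    """
    ref = reference.signatures
    if ref.shape != (config.n_celltypes, config.n_genes):
        raise ValueError(
            f"reference shape {ref.shape} does not match config "
            f"({config.n_celltypes} cell types x {config.n_genes} genes)"
        )
    genes = np.asarray(ref.columns)
    types = list(ref.index)
    marker_genes = {g for gs in reference.marker_map.values() for g in gs}

    rng_plant = substream(config.seed, "planted")
    non_marker = np.array([i for i, g in enumerate(genes) if g not in marker_genes])
    deg_idx = _pick_disjoint(rng_plant, non_marker, config.n_true_degs)
    signs = np.where(np.arange(config.n_true_degs) % 2 == 0, 1.0, -1.0)
    rng_plant.shuffle(signs)
    deg_effects = {str(genes[i]): float(s * config.deg_effect) for i, s in zip(deg_idx, signs)}

    remaining = np.setdiff1d(non_marker, deg_idx)
    gender_idx = _pick_disjoint(rng_plant, remaining, config.gender_gene_count)
    gender_genes = [str(g) for g in genes[gender_idx]]

    deg_vec = np.zeros(config.n_genes)
    for i, s in zip(deg_idx, signs):
        deg_vec[i] = s * config.deg_effect
    gender_vec = np.zeros(config.n_genes)
    gender_vec[gender_idx] = config.gender_effect

    ref_arr = ref.to_numpy()
    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    prop_rows: list[np.ndarray] = []

    for j, study in enumerate(config.study_ids):
        n_ctrl, n_case = config.n_per_group[j]
        rng_b = substream(config.seed, "batch", j)
        batch = rng_b.normal(0.0, config.study_sd, size=config.n_genes)
        rng_s = substream(config.seed, "study", j)

        for status, n_s, alpha in (
            ("control", n_ctrl, config.dirichlet_alpha_control),
            ("case", n_case, config.dirichlet_alpha_case),
        ):
            props = rng_s.dirichlet(alpha, size=n_s)
            males = rng_s.random(n_s) < config.male_fraction
            ages = np.round(rng_s.normal(75, 8, size=n_s)).astype(int)
            braak = rng_s.integers(3, 7, size=n_s) if status == "case" else rng_s.integers(0, 3, size=n_s)
            noise = rng_s.normal(0.0, config.noise_sd, size=(n_s, config.n_genes))
            mix = props @ ref_arr  # linear scale, strictly positive
            y = (
                np.log2(mix)
                + batch[None, :]
                + (deg_vec[None, :] if status == "case" else 0.0)
                + np.outer(males.astype(float), gender_vec)
                + noise
            )
            tag = "C" if status == "control" else "P"
            for s_i in range(n_s):
                sample = f"{study}_{tag}{s_i + 1:02d}"
                sample_ids.append(sample)
                meta_rows.append(
                    {
                        "sample_id": sample,
                        "study": study,
                        "status": status,
                        "gender": "M" if males[s_i] else "F",
                        "age": int(ages[s_i]),
                        "braak": int(braak[s_i]),
                    }
                )
                prop_rows.append(props[s_i])
            cols.append(y)

    expr = pd.DataFrame(np.vstack(cols).T, index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    true_props = pd.DataFrame(np.vstack(prop_rows), index=sample_ids, columns=types)

    truth = GroundTruth(
        true_proportions=true_props,
        deg_effects=deg_effects,
        marker_map=dict(reference.marker_map),
        gender_labels=meta["gender"].copy(),
        gender_genes=gender_genes,
        gender_effect=config.gender_effect,
    )
    return ExpressionSet(expr=expr, meta=meta), truth


def simulate_ppi(
    n_nodes: int, n_hubs: int, edge_density: float, seed: int
) -> pd.DataFrame:
    """A random simple graph with ``n_hubs`` planted high-degree hubs.

    Background edges follow an Erdos-Renyi G(n, edge_density) model; each
    planted hub is additionally wired to a random 35% of all nodes, so
    hubs dominate the degree distribution whenever the background
    density is appreciably below 0.35.  Returns an edge list with
    columns ``node_a``, ``node_b``, ``source``; no self-loops, no
    duplicate undirected pairs.
    """
    if not 0 < edge_density < 1:
        raise ValueError("edge_density must lie strictly between 0 and 1")
    if n_hubs >= n_nodes:
        raise ValueError("n_hubs must be smaller than n_nodes")
    if edge_density >= 0.3:
        raise ValueError("edge_density >= 0.3 would drown the planted hubs")

    rng = substream(seed, "ppi")
    width = len(str(n_nodes))
    names = [f"P{i + 1:0{width}d}" for i in range(n_nodes)]

    edges: set[tuple[int, int]] = set()
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(iu.size) < edge_density
    edges.update(zip(iu[mask].tolist(), ju[mask].tolist()))
    n_attach = max(int(np.ceil(0.35 * n_nodes)), int(np.ceil(0.3 * n_nodes)) + 1)
    for h in range(n_hubs):
        targets = rng.choice(n_nodes, size=n_attach, replace=False)
        for t in targets:
            if t == h:
                continue
            edges.add((min(h, t), max(h, t)))

    rows = sorted(edges)
    return pd.DataFrame(
        {
            "node_a": [names[i] for i, _ in rows],
            "node_b": [names[j] for _, j in rows],
            "source": "simulated",
        }
    )
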