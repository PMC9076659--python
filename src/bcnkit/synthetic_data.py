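"""Synthetic adolescent-cohort generator backed by a linear-Gaussian SEM.

The study data this package targets (longitudinal imaging + substance-use
cohorts) is typically access-restricted, so every pipeline stage is
exercised against cohorts simulated from a *known* structural equation
model: a DAG over the analysis variables with standardized edge weights,
unit marginal variances, additive site/sex nuisance effects and an
observation layer that splits the cortical-thickness variables into
left/right hemisphere measurements (inter-hemisphere correlation 0.8) at
two measurement waves.

The default model plants the focal arc ``cannabis_change -> dpfc_change``
with standardized coefficient -0.2 (implied marginal correlation about
-0.18, inside the plausible band for the reported -0.17), surrounds the
focal pair with colliders and multi-parent nodes so its orientation is
partially compelled, and wires the remaining variables with effects of
the magnitude seen in adolescent-cohort correlation tables (e.g.
SES -> baseline tobacco, puberty -> baseline alcohol).  A two-variable
model would be unidentifiable under score equivalence; the surrounding
structure is what makes direction recoverable at all.

Variables are continuous by default; an opt-in ordinal coarsening maps
the substance-use scores onto a right-skewed 7-point lifetime-use scale
(0 = never … 6 = 40+ times).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .graphs import DAG
from .preprocess import CohortTable

__all__ = [
    "GroundTruthModel",
    "HemisphereSplit",
    "default_ground_truth",
    "simulate",
    "implied_correlations",
    "ESPAD_CUTPOINTS",
]

# cutpoints on the latent standard-normal scale for the 7-point
# lifetime-use scale; most subjects land in the low categories
ESPAD_CUTPOINTS = (0.0, 0.55, 1.0, 1.4, 1.8, 2.2)

N_SITES = 8
DEFAULT_N = 637


@dataclass(frozen=True)
class HemisphereSplit:
    """Observation rule replacing a latent wave variable by two hemispheric
    columns with a given inter-hemisphere correlation."""

    latent: str
    left: str
    right: str
    correlation: float = 0.8


@dataclass
class GroundTruthModel:
    """Linear-Gaussian SEM: DAG + standardized weights + noise + nuisance.

    Every SEM node has unit marginal variance by construction (the noise
    standard deviations are solved from the weights), so the edge weights
    are standardized coefficients and the model-implied correlation matrix
    is available in closed form.
    """

    dag: DAG
    edge_weights: dict[tuple[str, str], float]
    site_effect_sd: float = 0.15
    sex_effect_sd: float = 0.15
    nuisance_seed: int = 20_240_101
    n_default: int = DEFAULT_N
    hemisphere_splits: tuple[HemisphereSplit, ...] = ()
    # latent wave pairs observed as baseline and baseline+change columns
    wave_pairs: tuple[tuple[str, str, str], ...] = ()  # (base, change, stem)
    ordinal_columns: tuple[str, ...] = ()
    ordinal_cutpoints: tuple[float, ...] = ESPAD_CUTPOINTS

    noise_sd: dict[str, float] = field(default_factory=dict)
    _implied: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for arc in self.dag.arcs:
            if arc not in self.edge_weights:
                raise InvalidInputError(f"arc {arc} has no weight")
        for arc in self.edge_weights:
            if arc not in self.dag.arcs:
                raise InvalidInputError(f"weight for unknown arc {arc}")
        self._solve_standardization()

    # -- closed-form second moments ----------------------------------------
    def _solve_standardization(self) -> None:
        """Solve noise variances so every node has marginal variance 1,
        building the implied covariance in topological order."""
        order = self.dag.topological_order()
        idx = {v: i for i, v in enumerate(order)}
        k = len(order)
        sigma = np.zeros((k, k))
        noise: dict[str, float] = {}
        for v in order:
            i = idx[v]
            pa = sorted(self.dag.parents(v))
            if pa:
                pidx = [idx[p] for p in pa]
                beta = np.array([self.edge_weights[(p, v)] for p in pa])
                spp = sigma[np.ix_(pidx, pidx)]
                explained = float(beta @ spp @ beta)
                if explained >= 1.0:
                    raise InvalidInputError(
                        f"weights into {v!r} imply variance >= 1; "
                        "reduce the coefficients"
                    )
                noise_var = 1.0 - explained
                # cov(v, u) = sum_p beta_p cov(p, u) for earlier u
                cov_row = beta @ sigma[pidx, :]
                sigma[i, :] = cov_row
                sigma[:, i] = cov_row
            else:
                noise_var = 1.0
            sigma[i, i] = 1.0
            noise[v] = float(np.sqrt(noise_var))
        self.noise_sd = noise
        nodes = list(self.dag.nodes)
        perm = [idx[v] for v in nodes]
        self._implied = pd.DataFrame(
            sigma[np.ix_(perm, perm)], index=nodes, columns=nodes
        )

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def implied_correlations(self) -> pd.DataFrame:
        """Exact model-implied correlation matrix over the SEM nodes."""
        return self._implied.copy()

    # -- fixed nuisance structure -------------------------------------------
    def nuisance_effects(self) -> tuple[dict[str, np.ndarray], dict[str, float]]:
        """Per-variable site offsets (8 levels, mean-zero) and sex effects,
        fixed by the model's nuisance seed (part of the model definition,
        independent of the sampling seed)."""
        rng = np.random.default_rng(self.nuisance_seed)
        site: dict[str, np.ndarray] = {}
        sex: dict[str, float] = {}
        for v in self.observed_columns():
            offs = rng.normal(0.0, self.site_effect_sd, size=N_SITES)
            site[v] = offs - offs.mean()
            sex[v] = float(rng.normal(0.0, self.sex_effect_sd))
        return site, sex

    def observed_columns(self) -> list[str]:
        """Columns that receive their own nuisance effects: hemispheric
        baseline and change components (the wave-19 measurement is their
        sum, so site/scanner effects persist across waves) plus every
        directly observed SEM node."""
        hidden = set()
        cols: list[str] = []
        for split in self.hemisphere_splits:
            hidden.add(split.latent)
        for base, change, stem in self.wave_pairs:
            hidden.add(base)
            hidden.add(change)
        for base, change, stem in self.wave_pairs:
            for suffix in ("lh", "rh"):
                cols.append(f"{stem}14_{suffix}")
                cols.append(f"{stem}_change_{suffix}")
        cols.extend(v for v in self.nodes if v not in hidden)
        return cols

    # ------------------------------------------------------------------ I/O
    def to_yaml(self) -> str:
        payload = {
            "nodes": list(self.nodes),
            "arcs": [
                {"from": a, "to": b, "weight": float(w)}
                for (a, b), w in sorted(self.edge_weights.items())
            ],
            "site_effect_sd": self.site_effect_sd,
            "sex_effect_sd": self.sex_effect_sd,
            "nuisance_seed": self.nuisance_seed,
            "n_default": self.n_default,
            "wave_pairs": [list(t) for t in self.wave_pairs],
            "hemisphere_splits": [
                {"latent": s.latent, "left": s.left, "right": s.right,
                 "correlation": s.correlation}
                for s in self.hemisphere_splits
            ],
            "ordinal_columns": list(self.ordinal_columns),
            "ordinal_cutpoints": list(self.ordinal_cutpoints),
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruthModel":
        payload = yaml.safe_load(text)
        arcs = [(a["from"], a["to"]) for a in payload["arcs"]]
        weights = {(a["from"], a["to"]): float(a["weight"])
                   for a in payload["arcs"]}
        return cls(
            dag=DAG(payload["nodes"], arcs),
            edge_weights=weights,
            site_effect_sd=float(payload.get("site_effect_sd", 0.15)),
            sex_effect_sd=float(payload.get("sex_effect_sd", 0.15)),
            nuisance_seed=int(payload.get("nuisance_seed", 20_240_101)),
            n_default=int(payload.get("n_default", DEFAULT_N)),
            wave_pairs=tuple(tuple(t) for t in payload.get("wave_pairs", [])),
            hemisphere_splits=tuple(
                HemisphereSplit(**d) for d in payload.get("hemisphere_splits", [])
            ),
            ordinal_columns=tuple(payload.get("ordinal_columns", [])),
            ordinal_cutpoints=tuple(
                payload.get("ordinal_cutpoints", ESPAD_CUTPOINTS)
            ),
        )


# ---------------------------------------------------------------------------
# default model
# ---------------------------------------------------------------------------

FOCAL_PAIR = ("cannabis_change", "dpfc_change")

_DEFAULT_NODES = (
    "dpfc_base", "dpfc_change",
    "cannabis_change",
    "tobacco_base", "tobacco_change",
    "alcohol_base", "alcohol_change",
    "handedness", "age_base", "cannabis_prs", "ses", "puberty",
    "adhd_base", "adhd_change", "trauma", "ss_base", "ss_change",
)

_DEFAULT_WEIGHTS: dict[tuple[str, str], float] = {
    ("age_base", "dpfc_base"): -0.13,
    ("age_base", "puberty"): 0.23,
    ("dpfc_base", "dpfc_change"): -0.50,
    ("dpfc_base", "tobacco_base"): -0.13,
    ("ses", "tobacco_base"): -0.16,
    ("ses", "adhd_base"): -0.10,
    ("puberty", "alcohol_base"): 0.15,
    ("tobacco_base", "alcohol_base"): 0.36,
    ("ss_base", "tobacco_base"): 0.12,
    ("ss_base", "alcohol_base"): 0.18,
    ("ss_base", "ss_change"): -0.49,
    ("ss_base", "cannabis_change"): 0.08,
    ("tobacco_base", "cannabis_change"): 0.18,
    ("tobacco_change", "cannabis_change"): 0.45,
    ("alcohol_base", "cannabis_change"): 0.14,
    ("cannabis_prs", "cannabis_change"): 0.10,
    ("cannabis_change", "dpfc_change"): -0.20,
    ("alcohol_base", "alcohol_change"): -0.32,
    ("tobacco_change", "alcohol_change"): 0.26,
    ("adhd_base", "adhd_change"): -0.56,
    ("adhd_base", "cannabis_change"): 0.08,
    ("adhd_base", "dpfc_change"): -0.08,
}


def default_ground_truth() -> GroundTruthModel:
    """The default 17-variable adolescent-cohort model.

    Plants ``cannabis_change -> dpfc_change`` at -0.2 amid colliders that
    partially compel its orientation; the two thickness factors are
    observed as left/right hemisphere columns (r = 0.8) at two waves.
    """
    dag = DAG(_DEFAULT_NODES, _DEFAULT_WEIGHTS.keys())
    return GroundTruthModel(
        dag=dag,
        edge_weights=dict(_DEFAULT_WEIGHTS),
        wave_pairs=(("dpfc_base", "dpfc_change", "dpfc"),),
        hemisphere_splits=(
            HemisphereSplit("dpfc_base", "dpfc14_lh", "dpfc14_rh", 0.8),
            HemisphereSplit("dpfc_change", "dpfc_change_lh", "dpfc_change_rh", 0.8),
        ),
        ordinal_columns=(
            "cannabis_change", "tobacco_base", "tobacco_change",
            "alcohol_base", "alcohol_change",
        ),
    )


def null_ground_truth() -> GroundTruthModel:
    """Same roster and nuisance structure, focal arc weight set to zero
    (the arc is removed); used for null calibration checks."""
    weights = {
        arc: w for arc, w in _DEFAULT_WEIGHTS.items() if arc != FOCAL_PAIR
    }
    dag = DAG(_DEFAULT_NODES, weights.keys())
    return GroundTruthModel(
        dag=dag,
        edge_weights=weights,
        wave_pairs=(("dpfc_base", "dpfc_change", "dpfc"),),
        hemisphere_splits=(
            HemisphereSplit("dpfc_base", "dpfc14_lh", "dpfc14_rh", 0.8),
            HemisphereSplit("dpfc_change", "dpfc_change_lh", "dpfc_change_rh", 0.8),
        ),
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def simulate(
    model: GroundTruthModel,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    ordinal: bool = False,
    keep_latent: bool = False,
) -> CohortTable:
    """Draw an n-subject cohort from the model.

    Nodes are sampled in topological order (node = sum of beta * parent +
    Gaussian noise), the hemisphere/wave observation layer is applied,
    then site offsets and a sex effect are added to every observed
    column.  Bit-reproducible for a given seed.

    Parameters
    ----------
    ordinal : bool
        Coarsen the model's ordinal columns onto the 7-point use scale.
    keep_latent : bool
        Also emit the latent thickness factors and the per-hemisphere
        true change columns (testing convenience).
    """
    n = int(n if n is not None else model.n_default)
    if n < 10:
        raise InvalidInputError("n must be >= 10")
    rng = np.random.default_rng(seed)
    order = model.dag.topological_order()
    values: dict[str, np.ndarray] = {}
    for v in order:
        eps = rng.normal(0.0, model.noise_sd[v], size=n)
        total = eps
        for p in sorted(model.dag.parents(v)):
            total = total + model.edge_weights[(p, v)] * values[p]
        values[v] = total

    # observation layer: hemisphere split of each latent wave variable
    hemis: dict[str, np.ndarray] = {}
    for split in model.hemisphere_splits:
        lam = np.sqrt(split.correlation)
        res = np.sqrt(1.0 - split.correlation)
        for name in (split.left, split.right):
            hemis[name] = lam * values[split.latent] + res * rng.normal(size=n)

    site = rng.integers(0, N_SITES, size=n)
    sex = rng.integers(0, 2, size=n)
    site_eff, sex_eff = model.nuisance_effects()

    def with_nuisance(name: str, vec: np.ndarray) -> np.ndarray:
        offs = site_eff.get(name)
        if offs is None:
            return vec
        return vec + offs[site] + sex_eff[name] * sex

    data: dict[str, np.ndarray] = {}
    true_changes: dict[str, np.ndarray] = {}
    for base, change, stem in model.wave_pairs:
        for suffix in ("lh", "rh"):
            b = hemis.get(f"{stem}14_{suffix}")
            c = hemis.get(f"{stem}_change_{suffix}")
            if b is None or c is None:
                raise InvalidInputError(
                    f"wave pair {stem!r} lacks hemisphere splits"
                )
            b = with_nuisance(f"{stem}14_{suffix}", b)
            c = with_nuisance(f"{stem}_change_{suffix}", c)
            data[f"{stem}14_{suffix}"] = b
            data[f"{stem}19_{suffix}"] = b + c
            true_changes[f"__true_change_{stem}_{suffix}"] = c
    hidden = {s.latent for s in model.hemisphere_splits}
    for base, change, stem in model.wave_pairs:
        hidden.add(base)
        hidden.add(change)
    for v in model.nodes:
        if v not in hidden:
            data[v] = with_nuisance(v, values[v])

    if ordinal:
        cuts = np.asarray(model.ordinal_cutpoints)
        for col in model.ordinal_columns:
            if col in data:
                data[col] = np.searchsorted(cuts, data[col]).astype(float)

    if keep_latent:
        for split in model.hemisphere_splits:
            data[f"__latent_{split.latent}"] = values[split.latent]
        data.update(true_changes)

    frame = pd.DataFrame(data, columns=list(data))
    nuisance = pd.DataFrame({"site": site.astype(int), "sex": sex.astype(int)})
    table = CohortTable(frame, nuisance)
    table.log(f"simulated n={n} from SEM (seed={seed}, ordinal={ordinal})")
    return table


def implied_correlations(model: GroundTruthModel) -> pd.DataFrame:
    """Exact model-implied correlation matrix (standardized models only)."""
    return model.implied_correlations()
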