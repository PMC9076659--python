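"""End-to-end orchestration of the network analysis.

The stages, mirroring how longitudinal-cohort network studies are run:

1. preprocess a raw cohort (hemisphere change scores, site/sex
   residualization, first-PC thickness composites);
2. build an arc blacklist from temporal variable roles (nothing may cause
   an exogenous trait; a change variable may not cause a baseline one);
3. run the full suite of structure-learning configurations (score-based,
   constraint-based, hybrid), each bootstrapped into arc
   strength/direction coefficients for the focal pair;
4. compare the two direction-restricted models for the focal pair by
   their penalized network fit (delta-BIC, positive = the
   exposure-to-outcome direction fits better);
5. serialize a deterministic JSON/TSV/DOT report.

Outputs are labelled "directional dependence under model assumptions":
arc directions are statements about penalized fit and conditional
independence, not experimental causal proof.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .ensemble import (
    AveragedNetwork,
    DEFAULT_B,
    DEFAULT_STRENGTH_THRESHOLD,
    bootstrap_learn,
    strength_direction,
    threshold_network,
)
from .exceptions import ConfigurationError, InvalidInputError
from .graphs import DAG, ArcConstraintSet
from .learners import LearnerConfig, make_learner
from .preprocess import CohortTable, PC1Composite, change_score, residualize
from .scoring import ScoreConfig, network_score

import numpy as np

__all__ = [
    "VariableRoles",
    "SuiteResult",
    "DirectionalComparison",
    "default_roles",
    "build_blacklist",
    "prepare_cohort",
    "run_suite",
    "directional_bic_comparison",
    "render_report",
    "TABLE_CONFIGS",
]

WAVES = ("baseline", "change", "timeless")


@dataclass(frozen=True)
class VariableRoles:
    """Temporal role of every analysis variable plus the focal ordered pair."""

    wave: dict[str, str]
    exogenous: frozenset[str]
    focal_pair: tuple[str, str]

    def __post_init__(self) -> None:
        for v, w in self.wave.items():
            if w not in WAVES:
                raise ConfigurationError(f"unknown wave {w!r} for {v!r}")
        unknown = set(self.exogenous) - set(self.wave)
        if unknown:
            raise ConfigurationError(f"exogenous variables without a role: {unknown}")
        a, b = self.focal_pair
        if a not in self.wave or b not in self.wave:
            raise ConfigurationError("focal pair members lack roles")

    @property
    def variables(self) -> list[str]:
        return list(self.wave)


def default_roles() -> VariableRoles:
    """Roles for the default synthetic cohort after preprocessing."""
    wave = {
        "dpfc14": "baseline",
        "dpfc_change": "change",
        "cannabis_change": "change",
        "tobacco_base": "baseline",
        "tobacco_change": "change",
        "alcohol_base": "baseline",
        "alcohol_change": "change",
        "handedness": "timeless",
        "age_base": "timeless",
        "cannabis_prs": "timeless",
        "ses": "timeless",
        "puberty": "baseline",
        "adhd_base": "baseline",
        "adhd_change": "change",
        "trauma": "timeless",
        "ss_base": "baseline",
        "ss_change": "change",
    }
    return VariableRoles(
        wave=wave,
        exogenous=frozenset(
            {"age_base", "handedness", "cannabis_prs", "ses", "trauma"}
        ),
        focal_pair=("cannabis_change", "dpfc_change"),
    )


def build_blacklist(
    roles: VariableRoles,
    extra: Sequence[tuple[str, str]] = (),
) -> ArcConstraintSet:
    """Arc blacklist from temporal logic.

    Forbidden: (i) any arc into an exogenous variable, (ii) any arc from a
    change variable into a baseline variable, (iii) user-supplied extra
    pairs.  Raises if the rules (plus extras) forbid the focal pair in
    both directions.
    """
    variables = roles.variables
    bl: set[tuple[str, str]] = set()
    for v in roles.exogenous:
        for u in variables:
            if u != v:
                bl.add((u, v))
    for u in variables:
        if roles.wave[u] != "change":
            continue
        for v in variables:
            if v != u and roles.wave[v] == "baseline":
                bl.add((u, v))
    bl.update((str(a), str(b)) for a, b in extra)
    a, b = roles.focal_pair
    if (a, b) in bl and (b, a) in bl:
        raise ConfigurationError(
            "blacklist forbids the focal pair in both directions"
        )
    return ArcConstraintSet(blacklist=bl)


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------


def prepare_cohort(
    raw: CohortTable, stems: Sequence[str] = ("dpfc",)
) -> tuple[CohortTable, dict]:
    """Raw simulated/acquired table -> analysis table.

    For each hemispheric wave stem (columns ``<stem>14_lh/rh`` and
    ``<stem>19_lh/rh``): per-hemisphere change scores, then site/sex
    residualization of everything, then first-PC composites ``<stem>14``
    (baseline) and ``<stem>_change``; raw hemisphere columns are dropped.
    Returns the analysis table and the composite diagnostics.
    """
    table = raw
    for stem in stems:
        for suffix in ("lh", "rh"):
            base, fu = f"{stem}14_{suffix}", f"{stem}19_{suffix}"
            if base not in table.data.columns or fu not in table.data.columns:
                raise InvalidInputError(f"missing hemisphere columns for {stem!r}")
            table = change_score(table, base, fu, name=f"{stem}_change_{suffix}")
        table.data = table.data.drop(
            columns=[f"{stem}19_lh", f"{stem}19_rh"]
        )
    table = residualize(table)
    diagnostics: dict[str, dict[str, float]] = {}
    for stem in stems:
        base_cols = [f"{stem}14_lh", f"{stem}14_rh"]
        change_cols = [f"{stem}_change_lh", f"{stem}_change_rh"]
        pc_base = PC1Composite(base_cols, name=f"{stem}14").fit(table)
        table = pc_base.transform(table)
        pc_change = PC1Composite(change_cols, name=f"{stem}_change").fit(table)
        table = pc_change.transform(table)
        diagnostics[stem] = {
            "baseline_eigenvalue": pc_base.eigenvalue_,
            "baseline_pct_variance": pc_base.pct_variance_,
            "change_eigenvalue": pc_change.eigenvalue_,
            "change_pct_variance": pc_change.pct_variance_,
        }
    return table, diagnostics


# ---------------------------------------------------------------------------
# the analysis suite
# ---------------------------------------------------------------------------

# the printed suite: 5 score-based, 4 constraint-based, 2 hybrid rows
TABLE_CONFIGS: tuple[dict, ...] = (
    {"label": "hc_bic_empty", "algorithm": "hc", "score": "bic",
     "start": "empty", "restarts": 0, "perturbations": 0},
    {"label": "hc_aic_empty", "algorithm": "hc", "score": "aic",
     "start": "empty", "restarts": 0, "perturbations": 0},
    {"label": "hc_bic_random", "algorithm": "hc", "score": "bic",
     "start": "random", "restarts": 0, "perturbations": 0},
    {"label": "hc_bic_perturb", "algorithm": "hc", "score": "bic",
     "start": "empty", "restarts": 5, "perturbations": 5},
    {"label": "tabu_bic", "algorithm": "tabu", "score": "bic"},
    {"label": "gs_mi", "algorithm": "gs", "ci_method": "mi-g"},
    {"label": "gs_fisher_z", "algorithm": "gs", "ci_method": "fisher-z"},
    {"label": "gs_pearson", "algorithm": "gs", "ci_method": "pearson"},
    {"label": "iamb_mi", "algorithm": "iamb", "ci_method": "mi-g"},
    {"label": "mmhc_bic_mi", "algorithm": "mmhc", "score": "bic",
     "ci_method": "mi-g"},
    {"label": "rsmax2_bic_mi", "algorithm": "rsmax2", "score": "bic",
     "ci_method": "mi-g"},
)


@dataclass
class SuiteResult:
    """Focal-pair strength/direction across the configured suite."""

    rows: pd.DataFrame
    focal_pair: tuple[str, str]
    B: int
    seed: Optional[int]
    threshold: float
    alpha: float
    primary_network: Optional[AveragedNetwork] = None
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _config_seed(master: Optional[int], index: int) -> int:
    state = np.random.SeedSequence([0 if master is None else master, index])
    return int(state.generate_state(1)[0] % (2**31))


def run_suite(
    data: CohortTable,
    roles: VariableRoles,
    B: int = DEFAULT_B,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    threshold: float = DEFAULT_STRENGTH_THRESHOLD,
    extra_blacklist: Sequence[tuple[str, str]] = (),
    configs: Sequence[dict] = TABLE_CONFIGS,
) -> SuiteResult:
    """Bootstrap every configured learner and tabulate the focal pair.

    Each row reports the focal pair's strength S and the direction
    coefficient D for the orientation exposure -> outcome given by
    ``roles.focal_pair``.  A hard failure in one configuration is recorded
    and the suite continues (partial result; ``SuiteResult.ok`` is False).
    """
    constraints = build_blacklist(roles, extra_blacklist)
    x, y = roles.focal_pair
    rows = []
    failures: list[str] = []
    primary: Optional[AveragedNetwork] = None
    for i, spec_row in enumerate(configs):
        spec_row = dict(spec_row)
        label = spec_row.pop("label", f"config_{i}")
        cfg = LearnerConfig(
            **spec_row, alpha=alpha, seed=_config_seed(seed, i)
        )
        try:
            ens = bootstrap_learn(
                data, cfg, constraints, B=B, seed=_config_seed(seed, 1000 + i)
            )
        except Exception as exc:
            failures.append(f"{label}: {exc}")
            rows.append(_suite_row(label, cfg, None, None))
            continue
        avg = strength_direction(ens)
        s = avg.strength(x, y)
        d = avg.direction(x, y) if s > 0 else None
        rows.append(_suite_row(label, cfg, s, d))
        if primary is None:
            primary = avg
    frame = pd.DataFrame(rows)
    return SuiteResult(
        rows=frame,
        focal_pair=roles.focal_pair,
        B=B,
        seed=seed,
        threshold=threshold,
        alpha=alpha,
        primary_network=primary,
        failures=failures,
    )


def _suite_row(label, cfg: LearnerConfig, s, d) -> dict:
    score_based = cfg.algorithm in ("hc", "tabu", "mmhc", "rsmax2")
    ci_based = cfg.algorithm in ("gs", "iamb", "mmhc", "rsmax2")
    return {
        "label": label,
        "algorithm": cfg.algorithm,
        "fit_criterion": cfg.score.upper() if score_based else "-",
        "start": cfg.start if cfg.algorithm in ("hc", "tabu") else "-",
        "perturbations": (
            "yes" if (cfg.algorithm == "hc" and cfg.restarts > 0) else
            ("no" if cfg.algorithm in ("hc", "tabu") else "-")
        ),
        "independence_test": cfg.ci_method if ci_based else "-",
        "strength": s,
        "direction": d,
    }


# ---------------------------------------------------------------------------
# direction-restricted model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectionalComparison:
    """Delta-BIC between the two direction-restricted models.

    ``delta_bic`` = score(model with only exposure -> outcome allowed)
    minus score(model with only outcome -> exposure allowed), on the
    higher-is-better scale; positive values favour the exposure-to-outcome
    direction.
    """

    pair: tuple[str, str]
    delta_bic: float
    score_forward_only: float
    score_reverse_only: float
    dag_forward: DAG
    dag_reverse: DAG


def directional_bic_comparison(
    data: CohortTable,
    pair: tuple[str, str],
    roles: Optional[VariableRoles] = None,
    cfg: Optional[LearnerConfig] = None,
    extra_blacklist: Sequence[tuple[str, str]] = (),
) -> DirectionalComparison:
    """Fit two models, each with one focal orientation blacklisted, and
    compare their penalized network fits."""
    x, y = pair
    cfg = cfg or LearnerConfig(algorithm="hc", score="bic")
    base: set[tuple[str, str]] = set(extra_blacklist)
    if roles is not None:
        base |= set(build_blacklist(roles).blacklist)
    base.discard((x, y))
    base.discard((y, x))
    score_cfg = ScoreConfig(cfg.score)

    def _fit(blocked: tuple[str, str]) -> tuple[DAG, float]:
        cons = ArcConstraintSet(blacklist=base | {blocked})
        learner = make_learner(cfg, cons).fit(data)
        dag = learner.dag_
        return dag, network_score(data, dag, score_cfg)

    dag_fwd, score_fwd = _fit((y, x))  # reverse blocked: only x -> y allowed
    dag_rev, score_rev = _fit((x, y))  # forward blocked: only y -> x allowed
    return DirectionalComparison(
        pair=pair,
        delta_bic=float(score_fwd - score_rev),
        score_forward_only=float(score_fwd),
        score_reverse_only=float(score_rev),
        dag_forward=dag_fwd,
        dag_reverse=dag_rev,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def render_report(
    suite: SuiteResult,
    avg: Optional[AveragedNetwork],
    out_dir: str,
    comparison: Optional[DirectionalComparison] = None,
    diagnostics: Optional[dict] = None,
) -> dict[str, str]:
    """Write the JSON run report, the full edge TSV and the thresholded
    summary graph (DOT + GraphML).  Deterministic: no timestamps, keys
    sorted.  Returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    report = {
        "note": "directional dependence under model assumptions",
        "focal_pair": list(suite.focal_pair),
        "bootstrap_B": suite.B,
        "seed": suite.seed,
        "alpha": suite.alpha,
        "strength_threshold": suite.threshold,
        "threshold_rule": "edges with strength strictly under the threshold are removed",
        "undirected_counting": "undirected arcs contribute 1/2 to each orientation",
        "delta_bic_sign": (
            "score(only exposure->outcome allowed) - "
            "score(only outcome->exposure allowed); positive favours "
            "exposure->outcome"
        ),
        "suite": suite.rows.to_dict(orient="records"),
        "failures": suite.failures,
    }
    if comparison is not None:
        report["delta_bic"] = comparison.delta_bic
        report["delta_bic_pair"] = list(comparison.pair)
    if diagnostics is not None:
        report["composite_diagnostics"] = diagnostics

    report_path = os.path.join(out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    paths["report"] = report_path

    if avg is not None:
        edges_path = os.path.join(out_dir, "edges.tsv")
        with open(edges_path, "w") as fh:
            fh.write(avg.to_tsv())
        paths["edges"] = edges_path
        summary = threshold_network(avg, suite.threshold)
        dot_path = os.path.join(out_dir, "summary.dot")
        with open(dot_path, "w") as fh:
            fh.write(summary.to_dot())
        paths["summary_dot"] = dot_path
        graphml_path = os.path.join(out_dir, "summary.graphml")
        summary.to_graphml(graphml_path)
        paths["summary_graphml"] = graphml_path
    return paths
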