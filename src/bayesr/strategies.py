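"""Scenario orchestration: FULL, per-chromosome CHR with phenotype
correction by high-density effects, KEPT re-analysis of retained variants,
and KEPT+HD augmentation, with explicit prior passing between stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .model import (DropSchedule, MixtureSpec, ModelData, PosteriorSummary,
                    VarianceComponents, run_em, run_mcmc, variance_components)
from .pedigree import Pedigree, build_A
from .simdata import GenotypePanel

STRATEGIES = ("HD_FULL", "S_FULL", "S_CHR", "S_KEPT", "S_KEPT_HD")


def child_seed(master: int, key: int) -> np.random.SeedSequence:
    """Deterministic per-stage/per-chromosome seed stream, order-independent."""
    return np.random.SeedSequence(entropy=master, spawn_key=(int(key),))


@dataclass
class ScenarioConfig:
    """Knobs of a single analysis stage (Table-of-scenarios style runs)."""

    strategy: str = "S_FULL"
    drop_proportion: float = 0.0
    drop_point: int | str | None = None  # "em" or MCMC iteration; None -> n_iter
    n_iter: int = 10_000
    post_drop_iter: int | None = None  # extra iterations when dropping at n_iter
    em_max_iter: int = 100
    em_tol: float = 1e-6
    h2_prior: float = 0.5
    seed: int = 0
    chr_gebv: str = "reestimated_only"
    compensation: str = "pseudo_counts"
    prior_from: str = "default"  # default | s_full | hd_full (pipeline chains)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not (0 <= self.drop_proportion < 1):
            raise ValueError("drop proportion must lie in [0, 1)")
        if self.chr_gebv not in ("reestimated_only", "reestimated_plus_hd_correction"):
            raise ValueError("chr_gebv mode not recognised")
        if self.prior_from not in ("default", "s_full", "hd_full"):
            raise ValueError("prior_from must be default, s_full or hd_full")

    def schedule(self) -> tuple[DropSchedule | None, int]:
        """Resolve the drop schedule and the total MCMC iteration count.

        Dropping at the final iteration extends the chain by
        ``post_drop_iter`` (default: another ``n_iter``) so the post-drop
        phase is actually sampled.
        """
        if self.drop_proportion == 0:
            return None, self.n_iter
        point = self.drop_point if self.drop_point is not None else self.n_iter
        total = self.n_iter
        if isinstance(point, int) and point >= self.n_iter:
            extra = self.post_drop_iter if self.post_drop_iter is not None else self.n_iter
            total = point + extra
        return DropSchedule(proportion=self.drop_proportion, drop_point=point), total


@dataclass
class StageResult:
    """One completed stage: posterior summary, effects, retained set, GEBV."""

    name: str
    summary: PosteriorSummary
    effects: pd.DataFrame
    retained_ids: np.ndarray
    gebv: pd.Series
    varcomp: VarianceComponents
    parent: str | None = None

    def __post_init__(self) -> None:
        if not set(self.retained_ids) <= set(self.effects["variant_id"]):
            raise ValueError("retained ids must be a subset of analysed ids")


@dataclass
class PredictionProblem:
    """A panel plus phenotypes, a validation split and optional pedigree.

    ``phenotype`` must contain columns ``id`` and ``value``; an optional
    ``weight`` column and any columns named in ``fixed_effects`` (levels are
    taken from the phenotype table).  Training records are the phenotype
    rows whose id is genotyped and not in the validation set.
    """

    panel: GenotypePanel
    phenotype: pd.DataFrame
    validation_ids: Sequence
    fixed_effects: tuple = ("breed",)
    pedigree: Pedigree | None = None

    def __post_init__(self) -> None:
        pheno = self.phenotype
        if "id" not in pheno.columns or "value" not in pheno.columns:
            raise ValueError("phenotype table needs 'id' and 'value' columns")
        if pheno["id"].duplicated().any():
            raise ValueError("duplicate phenotype ids")
        val = set(map(str, self.validation_ids))
        panel_pos = {str(i): j for j, i in enumerate(self.panel.iid)}
        rows, panel_rows = [], []
        for k, rid in enumerate(pheno["id"].astype(str)):
            if rid in panel_pos and rid not in val:
                rows.append(k)
                panel_rows.append(panel_pos[rid])
        if not rows:
            raise ValueError("no training records match the panel")
        # canonical record order = panel order, so shuffled phenotype rows
        # yield identical model inputs
        by_panel = np.argsort(panel_rows, kind="stable")
        rows = [rows[i] for i in by_panel]
        panel_rows = [panel_rows[i] for i in by_panel]
        self._train_pheno = pheno.iloc[rows].reset_index(drop=True)
        self.train_rows = np.asarray(panel_rows, dtype=np.int64)
        self.val_rows = np.asarray(
            [panel_pos[i] for i in map(str, self.validation_ids) if i in panel_pos],
            dtype=np.int64)
        self.y = self._train_pheno["value"].to_numpy(dtype=np.float64)
        self.weights = (self._train_pheno["weight"].to_numpy(dtype=np.float64)
                        if "weight" in pheno.columns
                        else np.ones(len(rows)))
        self.X = self._design_matrix()
        # centering constants from the training individuals only
        self.centers = self.panel.dosage[self.train_rows].mean(axis=0)
        self._Ainv = None
        self._rec_of = None
        if self.pedigree is not None:
            self._Ainv = build_A(self.pedigree).inverse()
            lookup = {str(v): i for i, v in enumerate(self.panel.iid[self.train_rows])}
            self._rec_of = np.array(
                [lookup.get(str(pid), -1) for pid in self.pedigree.ids],
                dtype=np.int64)

    def _design_matrix(self) -> np.ndarray:
        cols = [np.ones(len(self._train_pheno))]
        for name in self.fixed_effects:
            if name not in self._train_pheno.columns:
                raise ValueError(f"fixed-effect column {name!r} missing from phenotypes")
            levels = pd.unique(self._train_pheno[name])
            for lv in levels[1:]:  # reference-level coding
                cols.append((self._train_pheno[name] == lv).to_numpy(dtype=np.float64))
        X = np.column_stack(cols)
        keep = [0]
        for j in range(1, X.shape[1]):  # drop aliased columns
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
        return X[:, keep]

    @property
    def validation_panel(self) -> GenotypePanel:
        return self.panel.subset_individuals(self.val_rows)

    def default_spec(self, h2_prior: float, alpha=(1.0, 1.0, 1.0, 1.0)) -> MixtureSpec:
        """sigma_g2 = h2_prior x (weighted phenotypic variance after fixed effects)."""
        Xw = self.X * self.weights[:, None]
        bhat = np.linalg.solve(self.X.T @ Xw, Xw.T @ self.y)
        resid = self.y - self.X @ bhat
        var_adj = float(np.average(resid ** 2, weights=self.weights))
        return MixtureSpec(sigma_g2=max(h2_prior * var_adj, 1e-12), alpha=alpha)

    def model_data(self, variant_idx: np.ndarray | None = None,
                   y_override: np.ndarray | None = None) -> ModelData:
        idx = (np.arange(self.panel.n_variants) if variant_idx is None
               else np.asarray(variant_idx, dtype=np.int64))
        Wt = (self.panel.dosage[self.train_rows][:, idx].T.astype(np.float64)
              - self.centers[idx][:, None])
        return ModelData(
            y=self.y if y_override is None else y_override,
            X=self.X, Wt=Wt, weights=self.weights,
            chrom=self.panel.chrom[idx], pos=self.panel.pos[idx],
            variant_id=self.panel.variant_id[idx], centers=self.centers[idx],
            Ainv=self._Ainv, rec_of=self._rec_of)

    def variant_index(self, ids: Sequence) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.panel.variant_id)}
        missing = [x for x in ids if x not in lookup]
        if missing:
            raise ValueError(f"{len(missing)} variant id(s) not in panel, e.g. {missing[0]!r}")
        return np.array(sorted(lookup[x] for x in ids), dtype=np.int64)


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _fit_stage(problem: PredictionProblem, spec: MixtureSpec, config: ScenarioConfig,
               variant_idx: np.ndarray | None, seed_key: int,
               y_override: np.ndarray | None = None,
               schedule_override: tuple | None = None
               ) -> tuple[PosteriorSummary, ModelData]:
    data = problem.model_data(variant_idx, y_override)
    state = run_em(data, spec, max_iter=config.em_max_iter, tol=config.em_tol)
    schedule, total = config.schedule() if schedule_override is None else schedule_override
    summary = run_mcmc(state, data, spec, total, schedule=schedule,
                       seed=child_seed(config.seed, seed_key),
                       compensation=config.compensation)
    return summary, data


def _stage_result(name: str, summary: PosteriorSummary, data: ModelData,
                  problem: PredictionProblem, parent: str | None = None) -> StageResult:
    effects = summary.effect_table(centers=data.centers)
    retained = summary.variant_id[summary.active]
    gebv_vals = evaluation.predict_gebv(problem.validation_panel, effects)
    gebv = pd.Series(gebv_vals, index=problem.validation_panel.iid.astype(str))
    return StageResult(name=name, summary=summary, effects=effects,
                       retained_ids=np.asarray(retained), gebv=gebv,
                       varcomp=variance_components(summary, data), parent=parent)


def run_full(problem: PredictionProblem, spec: MixtureSpec, config: ScenarioConfig,
             variant_idx: np.ndarray | None = None, seed_key: int = 0,
             name: str = "FULL") -> StageResult:
    """One EM + MCMC run over all (or the given subset of) variants."""
    summary, data = _fit_stage(problem, spec, config, variant_idx, seed_key)
    return _stage_result(name, summary, data, problem)


def _resolve_effects(problem: PredictionProblem,
                     effects: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    lookup = {v: i for i, v in enumerate(problem.panel.variant_id)}
    eff_col = ("posterior_mean_effect" if "posterior_mean_effect" in effects.columns
               else "effect")
    idx, eff = [], []
    for _, row in effects.iterrows():
        if row["variant_id"] not in lookup:
            raise ValueError(f"HD effect variant {row['variant_id']!r} not in panel")
        idx.append(lookup[row["variant_id"]])
        eff.append(row[eff_col])
    return np.asarray(idx, dtype=np.int64), np.asarray(eff, dtype=np.float64)


def hd_corrected_phenotypes(problem: PredictionProblem,
                            hd_effects: pd.DataFrame) -> dict[int, np.ndarray]:
    """Per chromosome c: y_c = y - sum over other chromosomes of W v_hd.

    Uses the training dosages and the problem's centering constants; the
    focal chromosome's own HD contribution is left in the response.
    """
    chroms = np.unique(problem.panel.chrom)
    hd_idx, hd_eff = _resolve_effects(problem, hd_effects)
    hd_chrom = problem.panel.chrom[hd_idx]
    missing = set(chroms) - set(np.unique(hd_chrom))
    if len(chroms) > 1 and missing:
        raise ValueError(f"HD effects cover no variants on chromosome(s) {sorted(missing)}")
    train_dos = problem.panel.dosage[problem.train_rows].astype(np.float64)
    contrib = {}
    for c in chroms:
        sel = hd_idx[hd_chrom == c]
        contrib[int(c)] = (train_dos[:, sel] - problem.centers[sel]) @ hd_eff[hd_chrom == c]
    total = sum(contrib.values())
    return {c: problem.y - (total - g) for c, g in contrib.items()}


def run_per_chromosome(problem: PredictionProblem, spec: MixtureSpec,
                       config: ScenarioConfig, hd_effects: pd.DataFrame,
                       name: str = "CHR", parent: str | None = None) -> StageResult:
    """Analyse each chromosome separately against HD-corrected phenotypes.

    For chromosome c the response is y - sum_{c' != c} W_{c'} v_hd,{c'},
    where the correction uses the posterior-mean effects (and centering
    constants) of a completed HD FULL stage.  Fixed effects and the
    polygenic term are refitted within every sub-model.  Chromosome runs
    use independent child seed streams keyed by chromosome number, so the
    output is invariant to execution order.
    """
    chroms = np.unique(problem.panel.chrom)
    if chroms.size == 0:
        raise ValueError("panel has no variants")
    hd_idx, hd_eff = _resolve_effects(problem, hd_effects)
    corrected = hd_corrected_phenotypes(problem, hd_effects)

    val_panel = problem.validation_panel
    pieces, summaries = [], {}
    for c in chroms:
        idx_c = np.nonzero(problem.panel.chrom == c)[0]
        summary, data = _fit_stage(problem, spec, config, idx_c, seed_key=int(c),
                                   y_override=corrected[int(c)])
        summaries[int(c)] = (summary, data)
        pieces.append(summary.effect_table(centers=data.centers))

    effects = pd.concat(pieces, ignore_index=True)
    retained = np.concatenate([s.variant_id[s.active] for s, _ in summaries.values()])
    gebv_vals = evaluation.predict_gebv(val_panel, effects)
    if config.chr_gebv == "reestimated_plus_hd_correction":
        # model-implied average: each sub-model predicts its own chromosome
        # plus the HD contribution of the others; averaging over chromosomes
        # gives (1/C) * sum_c W_c v_c + (C-1)/C * HD prediction
        val_dos = val_panel.dosage.astype(np.float64)
        hd_pred = (val_dos[:, hd_idx] - problem.centers[hd_idx]) @ hd_eff
        n_chr = len(chroms)
        gebv_vals = gebv_vals / n_chr + hd_pred * (n_chr - 1) / n_chr

    # genome-wide summary stitched from the per-chromosome pieces
    panel_order = {v: i for i, v in enumerate(problem.panel.variant_id)}
    order = np.argsort([panel_order[vid] for vid in effects["variant_id"]])
    effects = effects.iloc[order].reset_index(drop=True)
    first = next(iter(summaries.values()))[0]
    stitched = PosteriorSummary(
        variant_id=effects["variant_id"].to_numpy(),
        chrom=effects["chrom"].to_numpy(), pos=effects["pos"].to_numpy(),
        v_mean=effects["posterior_mean_effect"].to_numpy(),
        pip=effects["pip"].to_numpy(),
        class_prob=effects[[f"p_class{k + 1}" for k in range(4)]].to_numpy(),
        occupancy=np.sum([s.occupancy for s, _ in summaries.values()], axis=0),
        P_mean=np.mean([s.P_mean for s, _ in summaries.values()], axis=0),
        b_mean=first.b_mean, a_mean=first.a_mean,
        sigma_e2_mean=float(np.mean([s.sigma_e2_mean for s, _ in summaries.values()])),
        sigma_a2_mean=float(np.mean([s.sigma_a2_mean for s, _ in summaries.values()])),
        n_iter=first.n_iter, active=~effects["dropped"].to_numpy(),
        drop_iter=effects["drop_iter"].to_numpy(),
        # chromosomes analysed independently: variances add
        marker_var_mean=float(sum(s.marker_var_mean for s, _ in summaries.values())))
    full_data = problem.model_data()
    gebv = pd.Series(gebv_vals, index=val_panel.iid.astype(str))
    return StageResult(name=name, summary=stitched, effects=effects,
                       retained_ids=retained, gebv=gebv,
                       varcomp=variance_components(stitched, full_data), parent=parent)


def rescaled_prior(class_counts: np.ndarray, n_variants: int) -> tuple:
    """Posterior class counts rescaled so the pseudo-counts sum to n_variants."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.sum() <= 0:
        raise ValueError("class counts must be positive")
    alpha = counts / counts.sum() * n_variants
    return tuple(np.maximum(alpha, 1e-6))


def run_kept(problem: PredictionProblem, spec: MixtureSpec, config: ScenarioConfig,
             selection_ids: Sequence, prior_counts: np.ndarray | None = None,
             seed_key: int = 0, name: str = "KEPT",
             parent: str | None = None) -> StageResult:
    """Fresh genome-wide EM + MCMC restricted to the selected variants.

    ``prior_counts`` (posterior class counts of an earlier run) initialise
    the Dirichlet prior after rescaling to the retained variant count; when
    omitted the spec's default alpha is used.
    """
    ids = list(selection_ids)
    if not ids:
        raise ValueError("empty variant selection")
    idx = problem.variant_index(ids)
    stage_spec = spec if prior_counts is None else replace(
        spec, alpha=rescaled_prior(prior_counts, len(idx)))
    summary, data = _fit_stage(problem, stage_spec, config, idx, seed_key)
    return _stage_result(name, summary, data, problem, parent=parent)


def run_kept_plus_hd(problem: PredictionProblem, spec: MixtureSpec,
                     config: ScenarioConfig, selection_ids: Sequence,
                     hd_ids: Sequence, prior_counts: np.ndarray | None = None,
                     seed_key: int = 0, name: str = "KEPT_HD",
                     parent: str | None = None) -> StageResult:
    """run_kept over the union of the retained selection and the HD variants."""
    union = list(dict.fromkeys(list(selection_ids) + list(hd_ids)))
    if not union:
        raise ValueError("empty union of selection and HD variants")
    return run_kept(problem, spec, config, union, prior_counts=prior_counts,
                    seed_key=seed_key, name=name, parent=parent)


# ---------------------------------------------------------------------------
# scenario chains
# ---------------------------------------------------------------------------

def run_pipeline(problem: PredictionProblem, config: ScenarioConfig,
                 spec: MixtureSpec | None = None) -> dict[str, StageResult]:
    """Run the stage chain a strategy needs and return all results by name.

    HD_FULL analyses the variants annotated "HD"; S_CHR corrects phenotypes
    with HD_FULL effects; S_KEPT / S_KEPT_HD re-analyse the CHR-retained
    variants, taking their prior from the run named by ``config.prior_from``.
    """
    if spec is None:
        spec = problem.default_spec(config.h2_prior)
    results: dict[str, StageResult] = {}

    hd_mask = problem.panel.annotation == "HD"
    if config.strategy == "HD_FULL" or config.strategy in ("S_CHR", "S_KEPT", "S_KEPT_HD"):
        if not hd_mask.any():
            raise ValueError("no variants annotated 'HD' in the panel")
        hd_config = replace(config, drop_proportion=0.0, drop_point=None)
        results["HD_FULL"] = run_full(problem, spec, hd_config,
                                      variant_idx=np.nonzero(hd_mask)[0],
                                      name="HD_FULL")
    if config.strategy == "HD_FULL":
        return results
    if config.strategy == "S_FULL":
        results["S_FULL"] = run_full(problem, spec, config, name="S_FULL")
        return results

    results["S_CHR"] = run_per_chromosome(
        problem, spec, config, results["HD_FULL"].effects,
        name="S_CHR", parent="HD_FULL")
    if config.strategy == "S_CHR":
        return results

    if config.prior_from == "default":
        prior_counts = None
    elif config.prior_from == "hd_full":
        prior_counts = results["HD_FULL"].summary.occupancy
    else:  # s_full
        results["S_FULL"] = run_full(problem, spec, config, name="S_FULL")
        prior_counts = results["S_FULL"].summary.occupancy

    selection = results["S_CHR"].retained_ids
    if config.strategy == "S_KEPT":
        results["S_KEPT"] = run_kept(problem, spec, config, selection,
                                     prior_counts=prior_counts, name="S_KEPT",
                                     parent="S_CHR")
    else:
        hd_ids = problem.panel.variant_id[hd_mask]
        results["S_KEPT_HD"] = run_kept_plus_hd(
            problem, spec, config, selection, hd_ids,
            prior_counts=prior_counts, name="S_KEPT_HD", parent="S_CHR")
    return results
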