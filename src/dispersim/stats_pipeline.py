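"""Trend models over derived per-turn tables.

Linear mixed models are fit by REML via statsmodels' MixedLM. The primary
grouping factor (the first requested random intercept, normally the dyad)
becomes the model's groups; further intercepts and any random slopes for
non-primary factors enter as variance components. When the maximal model
fails to converge or is singular, random slopes are removed one at a time in
a fixed priority order — slopes for the primary (pair) group before slopes
for other factors, interaction slopes before main-effect slopes — and the
reduction is recorded in the result, so the protocol is deterministic.

Denominator degrees of freedom use a residual approximation
(n_obs - rank of the fixed-effects design); exact Satterthwaite df are not
reproduced, and the acceptance surface is the sign and magnitude of the
fixed-effect estimates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .game_model import GameLog
from .metrics import (
    mean_pairwise_distance,
    quintile_areas,
    rolling_dispersion,
    turn_series,
)
from .null_model import empirical_p, generate_null

__all__ = [
    "TrendFitResult",
    "build_turn_table",
    "fit_trend",
    "first_signal_analysis",
    "report",
]

LOG_AREA_EPS = 1e-6  # degenerate clouds have area 0; log uses log(area + eps)


@dataclass
class TrendFitResult:
    """Tidy summary of one mixed-model fit.

    ``coefficients`` has one row per fixed effect with estimate, SE, t,
    approximate df, and p; ``random_structure`` describes the structure that
    actually converged and ``dropped_slopes`` the reduction that led to it.
    """

    dependent: str
    coefficients: pd.DataFrame
    random_structure: str
    dropped_slopes: List[str]
    converged: bool
    n_obs: int
    formula: str

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])

    def to_frame(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out.insert(0, "dependent", self.dependent)
        out["random_structure"] = self.random_structure
        out["converged"] = self.converged
        out["n_obs"] = self.n_obs
        return out.reset_index(names="term")


def build_turn_table(logs: Sequence[GameLog]) -> pd.DataFrame:
    """Concatenate per-turn derived variables over dyads, one row per trial.

    Missing values (first occurrences, early turns) stay explicit as NaN.
    Condition is coded with outer_edge as the reference level.
    """
    columns = [
        "pair_id", "condition", "turn", "sender_id", "referent_id", "x", "y",
        "correct", "dist_center", "extremeness", "auto_distance",
        "partner_distance", "rolling_dispersion",
        "last_outcome_same_referent", "quintile", "turns_since_new_referent",
        "referent_set", "s", "active_set_size",
    ]
    if not logs:
        return pd.DataFrame(columns=columns)
    table = pd.concat([turn_series(log) for log in logs], ignore_index=True)
    table["condition"] = pd.Categorical(
        table["condition"], categories=["outer_edge", "inner_edge"]
    )
    return table[columns]


def _slope_priority(
    random_slopes: Sequence[Tuple[str, str]], primary: str
) -> List[Tuple[str, str]]:
    """Drop order: primary-group slopes first, interaction slopes before
    main-effect slopes within each tier."""

    def key(item: Tuple[str, str]):
        group, var = item
        return (0 if group == primary else 1, 0 if ":" in var else 1, group, var)

    return sorted(random_slopes, key=key)


def fit_trend(
    table: pd.DataFrame,
    dependent: str,
    fixed: Sequence[str],
    interactions: Sequence[str] = (),
    random_intercepts: Sequence[str] = ("pair_id",),
    random_slopes: Sequence[Tuple[str, str]] = (),
) -> TrendFitResult:
    """Fit a linear mixed model with a deterministic reduction protocol.

    ``random_slopes`` is a list of (grouping factor, variable) pairs. The
    maximal requested structure is attempted first; on non-convergence or a
    singular random-effects covariance, slopes are dropped one at a time in
    priority order. If no random intercept can be fit either, the result is
    returned with ``converged=False`` and an empty coefficient table —
    never a silent fallback.
    """
    if not random_intercepts:
        raise ValueError("at least one random intercept is required")
    terms = list(fixed) + [i for i in interactions if i not in fixed]
    formula = f"{dependent} ~ " + (" + ".join(terms) if terms else "1")
    needed = {dependent, *random_intercepts}
    for t in list(fixed) + list(interactions):
        for piece in t.replace("*", ":").split(":"):
            needed.add(piece.strip())
    data = table.dropna(subset=[c for c in needed if c in table.columns]).copy()
    primary = random_intercepts[0]

    drop_order = _slope_priority(random_slopes, primary)
    # structures to try: maximal, then removing slopes one by one
    attempts: List[List[Tuple[str, str]]] = []
    current = list(random_slopes)
    attempts.append(list(current))
    for victim in drop_order:
        current = [s for s in current if s != victim]
        attempts.append(list(current))
    # dedupe consecutive identical structures
    seen, structures = set(), []
    for a in attempts:
        key = tuple(sorted(a))
        if key not in seen:
            seen.add(key)
            structures.append(a)

    def try_structure(slopes, boundary_ok=False):
        """Fit one random-effects structure; returns (result bundle, error)."""
        re_vars = [v for g, v in slopes if g == primary]
        re_formula = "1 + " + " + ".join(re_vars) if re_vars else "1"
        vc: Dict[str, str] = {}
        for g in random_intercepts[1:]:
            vc[g] = f"0 + C({g})"
        for g, v in slopes:
            if g != primary:
                vc[f"{g}__{v}"] = f"0 + C({g}):{v}"
        error = None
        # optimizer sequence is fixed, so the whole protocol is deterministic
        for method in (None, ["lbfgs"], ["powell"]):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    model = smf.mixedlm(
                        formula,
                        data=data,
                        groups=data[primary],
                        re_formula=re_formula,
                        vc_formula=vc or None,
                    )
                    result = (
                        model.fit(reml=True)
                        if method is None
                        else model.fit(reml=True, method=method)
                    )
                    fe = result.fe_params
                    se = result.bse_fe
            except (np.linalg.LinAlgError, ValueError, KeyError) as exc:
                error = f"{type(exc).__name__}: {exc}"
                continue
            singular = False
            if re_vars:
                eigs = np.linalg.eigvalsh(np.asarray(result.cov_re, dtype=float))
                singular = bool(eigs.min() < 1e-8)
            if slopes and not singular:
                slope_vc = [
                    i for i, name in enumerate(model.exog_vc.names) if "__" in name
                ]
                if any(result.vcomp[i] < 1e-8 for i in slope_vc):
                    singular = True
            healthy = (
                result.converged
                and not (slopes and singular)
                and np.all(np.isfinite(se))
                and np.all(np.asarray(se) > 0)
            )
            if not healthy:
                error = "singular fit" if singular else "boundary fit"
                if not (boundary_ok and np.all(np.isfinite(np.asarray(fe)))):
                    continue
            k = np.linalg.matrix_rank(model.exog)
            df = max(len(data) - k, 1)
            se = np.asarray(se, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                tvals = np.asarray(fe) / se
                pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
            coefs = pd.DataFrame(
                {
                    "estimate": np.asarray(fe, dtype=float),
                    "se": se,
                    "t": tvals,
                    "df": float(df),
                    "p": pvals,
                },
                index=list(model.exog_names),
            )
            dropped = [
                f"{g}:{v}" for g, v in random_slopes if (g, v) not in slopes
            ]
            structure = f"groups={primary}; re_formula={re_formula}"
            if vc:
                structure += f"; vc={sorted(vc)}"
            if not healthy:
                structure += " [boundary]"
            return (
                TrendFitResult(
                    dependent=dependent,
                    coefficients=coefs,
                    random_structure=structure,
                    dropped_slopes=dropped,
                    converged=bool(healthy),
                    n_obs=len(data),
                    formula=formula,
                ),
                None,
            )
        return None, error

    last_error: Optional[str] = None
    for slopes in structures:
        fit, err = try_structure(slopes)
        if fit is not None:
            return fit
        last_error = err
    # last resort: accept an intercepts-only boundary fit (e.g. zero residual
    # or zero group variance) with finite estimates, flagged as such
    fit, err = try_structure([], boundary_ok=True)
    if fit is not None:
        return fit
    last_error = err or last_error

    return TrendFitResult(
        dependent=dependent,
        coefficients=pd.DataFrame(
            columns=["estimate", "se", "t", "df", "p"]
        ),
        random_structure=f"unfittable ({last_error})",
        dropped_slopes=[f"{g}:{v}" for g, v in random_slopes],
        converged=False,
        n_obs=len(data),
        formula=formula,
    )


def first_signal_analysis(logs: Sequence[GameLog]) -> Dict[str, object]:
    """Initial-behavior analysis: each player's very first signal.

    Fits y ~ x with a random intercept for referent (a positive slope is the
    diagonal comfort-band signature) and reports per-condition mean distance
    from the pad center of first signals.
    """
    rows = []
    for log in logs:
        seen = set()
        for t in log:
            if t.sender_id not in seen:
                seen.add(t.sender_id)
                p = t.first_point
                rows.append(
                    {
                        "pair_id": log.pair_id,
                        "condition": log.condition.value,
                        "referent_id": t.referent_id,
                        "x": p.x,
                        "y": p.y,
                        "dist_center": np.hypot(p.x - 0.5, p.y - 0.5),
                    }
                )
            if len(seen) == 2:
                break
    table = pd.DataFrame(rows)
    fit = fit_trend(
        table,
        dependent="y",
        fixed=["x"],
        random_intercepts=["referent_id"],
    )
    means = (
        table.groupby("condition")["dist_center"].mean().to_dict()
        if len(table)
        else {}
    )
    return {"fit": fit, "mean_dist_center_by_condition": means, "table": table}


def _final_dispersion(log: GameLog) -> Optional[float]:
    return rolling_dispersion(log, log.trials[-1].turn) if len(log) else None


def _pair_convergence_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-pair mean auto- and partner distance (for the convergence r)."""
    return (
        table.groupby("pair_id", observed=True)[
            ["auto_distance", "partner_distance"]
        ]
        .mean()
        .dropna()
    )


def report(
    logs: Sequence[GameLog],
    out_dir: "str | Path",
    seed: int = 0,
    n_null: int = 100_000,
) -> Dict[str, object]:
    """Run the full analysis battery over a set of game logs.

    Covers initial behavior (first-signal x-y relation, distance-from-center
    trend), dispersion over time (quintile areas, extremeness, auto-
    distance), convergence (partner distance, last-outcome contrast, the
    auto/partner correlation), and the Monte Carlo null comparison for final
    dispersion. Writes turn_table.csv, fits.csv, quintile_areas.csv,
    null_comparison.csv and summary.json to ``out_dir``. Failures of single
    analyses are recorded per entry, never fatal for the bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = build_turn_table(logs)
    table.to_csv(out / "turn_table.csv", index=False)

    entries: Dict[str, object] = {}
    fits: List[TrendFitResult] = []

    def run(name, fn):
        try:
            entries[name] = fn()
        except Exception as exc:  # recorded, not fatal
            entries[name] = {"error": f"{type(exc).__name__}: {exc}"}

    multi_condition = table["condition"].nunique() > 1

    def trend(dep, fixed, **kw):
        if multi_condition:
            fixed = list(fixed) + ["condition"]
            kw.setdefault("interactions", [f"{fixed[0]}:condition"])
        fit = fit_trend(table, dep, fixed, **kw)
        fits.append(fit)
        return fit

    run("first_signals", lambda: first_signal_analysis(logs))
    run(
        "dist_center_trend",
        lambda: trend(
            "dist_center", ["turn"], random_intercepts=["pair_id", "referent_id"]
        ),
    )
    run(
        "auto_distance_trend",
        lambda: trend(
            "auto_distance", ["turn"], random_intercepts=["pair_id", "referent_id"]
        ),
    )
    run(
        "partner_distance_trend",
        lambda: trend(
            "partner_distance",
            ["turn"],
            random_intercepts=["pair_id", "referent_id"],
        ),
    )
    run(
        "extremeness_trend",
        lambda: trend(
            "extremeness", ["turn"], random_intercepts=["pair_id", "referent_id"]
        ),
    )
    run(
        "last_outcome_contrast",
        lambda: trend(
            "partner_distance",
            ["last_outcome_same_referent", "turn"],
            random_intercepts=["pair_id", "referent_id"],
        ),
    )
    run(
        "new_referent_destabilization",
        lambda: trend(
            "auto_distance",
            ["turns_since_new_referent", "turn"],
            random_intercepts=["pair_id", "referent_id"],
        ),
    )

    # quintile signal areas and their log-area trend
    def quintile_analysis():
        rows = []
        for log in logs:
            for cs in quintile_areas(log):
                rows.append(
                    {
                        "pair_id": log.pair_id,
                        "condition": log.condition.value,
                        "referent_id": cs.referent_id,
                        "referent_set": cs.referent_id // 4 + 1,
                        "quintile": cs.quintile,
                        "n_points": cs.n_points,
                        "area": cs.area,
                    }
                )
        qa = pd.DataFrame(rows)
        qa.to_csv(out / "quintile_areas.csv", index=False)
        qa["log_area"] = np.log(qa["area"] + LOG_AREA_EPS)
        fit = fit_trend(
            qa,
            dependent="log_area",
            fixed=["quintile"]
            + (["condition"] if qa["condition"].nunique() > 1 else []),
            random_intercepts=["pair_id"],
        )
        fits.append(fit)
        return {
            "fit": fit,
            "mean_area_by_quintile": qa.groupby("quintile")["area"].mean().to_dict(),
            "mean_area_by_set": qa.groupby("referent_set")["area"].mean().to_dict(),
        }

    run("quintile_areas", quintile_analysis)

    def convergence():
        pc = _pair_convergence_table(table)
        if len(pc) >= 3:
            r, p = sps.pearsonr(pc["auto_distance"], pc["partner_distance"])
        else:
            r, p = float("nan"), float("nan")
        return {"r": float(r), "p": float(p), "n_pairs": int(len(pc))}

    run("auto_partner_correlation", convergence)

    def null_comparison():
        rows = []
        for i, log in enumerate(logs):
            disp = _final_dispersion(log)
            if disp is None:
                continue
            latest = {t.referent_id for t in log if t.correct}
            size = max(len(latest), 2)
            null = generate_null(
                "pairwise", size, n_null, log.condition, seed=seed + i
            )
            rows.append(
                {
                    "pair_id": log.pair_id,
                    "condition": log.condition.value,
                    "final_dispersion": disp,
                    "inventory_size": size,
                    "null_mean": null.mean,
                    "p_upper": empirical_p(disp, null, "upper"),
                }
            )
        nc = pd.DataFrame(rows)
        nc.to_csv(out / "null_comparison.csv", index=False)
        return {
            "mean_final_dispersion": float(nc["final_dispersion"].mean()),
            "mean_null": float(nc["null_mean"].mean()),
            "n_pairs": int(len(nc)),
        }

    run("null_comparison", null_comparison)

    if fits:
        pd.concat([f.to_frame() for f in fits], ignore_index=True).to_csv(
            out / "fits.csv", index=False
        )

    def jsonable(obj):
        if isinstance(obj, TrendFitResult):
            return {
                "dependent": obj.dependent,
                "converged": obj.converged,
                "random_structure": obj.random_structure,
                "dropped_slopes": obj.dropped_slopes,
                "coefficients": obj.coefficients.to_dict(orient="index"),
            }
        if isinstance(obj, pd.DataFrame):
            return f"<table with {len(obj)} rows>"
        if isinstance(obj, dict):
            return {str(k): jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        return obj

    with open(out / "summary.json", "w") as fh:
        json.dump({k: jsonable(v) for k, v in entries.items()}, fh, indent=2)
    return entries
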