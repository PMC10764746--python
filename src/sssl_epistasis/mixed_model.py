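"""Mixed linear model for multi-environment trials of genetic materials.

The observation model is

    y_hjk = mu + E_h + G_j + GE_hj + B_k(h) + e_hjk

with mu and the environment effects E treated as fixed and the genotypic
effects G, the genotype-by-environment interactions GE, the blocks nested
in environments B and the plot error e treated as random.  The module
provides

* a joint ANOVA with expected-mean-square (EMS) bookkeeping,
* MINQUE(1) variance components (minimum-norm quadratic unbiased
  estimation with all prior values set to 1, single pass),
* the ANOVA/EMS method-of-moments components as an independent route,
* BLUP prediction of G and GE from Henderson's mixed-model equations, and
  the unshrunken least-squares predictions used for contrast t-tests,
* general (G share) and peculiar (GE share) heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import ErrorContext

COMPONENTS = ("G", "GE", "B", "e")


def as_plot_frame(plots) -> pd.DataFrame:
    """Normalize plot input (DataFrame or PlotRecord iterable) to a frame."""
    if isinstance(plots, pd.DataFrame):
        df = plots.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "env": p.environment,
                    "block": p.block,
                    "material": p.material,
                    "hd": p.hd,
                }
                for p in plots
            ]
        )
    missing = {"env", "block", "material", "hd"} - set(df.columns)
    if missing:
        raise ValueError(f"plot table missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("plot table is empty")
    return df


@dataclass
class Layout:
    environments: List[str]
    blocks: Dict[str, List[str]]
    materials: List[str]

    @property
    def n_env(self) -> int:
        return len(self.environments)

    @property
    def n_blocks(self) -> int:
        counts = {len(b) for b in self.blocks.values()}
        if len(counts) != 1:
            raise ValueError("unequal block counts across environments")
        return counts.pop()

    @property
    def n_materials(self) -> int:
        return len(self.materials)


def _layout(df: pd.DataFrame) -> Layout:
    envs = sorted(df["env"].astype(str).unique())
    mats = sorted(df["material"].astype(str).unique())
    blocks = {
        env: sorted(df.loc[df["env"].astype(str) == env, "block"].astype(str).unique())
        for env in envs
    }
    return Layout(environments=envs, blocks=blocks, materials=mats)


# ---------------------------------------------------------------------------
# joint ANOVA with EMS bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Joint ANOVA over environments with blocks nested in environments.

    ``table`` rows: environments, blocks_within_env, genotypes, GxE, error
    (zero-df sources are dropped).  ``ems`` holds per-source EMS
    coefficients on (sigma2_e, sigma2_B, sigma2_GE, sigma2_G); the fixed
    environment term contributes an additional quadratic not listed there.
    F tests use the EMS-appropriate denominators for the random model:
    genotypes against GxE, GxE and blocks against error, environments
    against blocks.
    """

    table: pd.DataFrame
    ems: pd.DataFrame
    layout: Layout

    @property
    def error_ms(self) -> float:
        return float(self.table.loc["error", "mean_sq"])

    @property
    def error_df(self) -> int:
        return int(self.table.loc["error", "df"])

    def error_context(self) -> ErrorContext:
        return ErrorContext(
            sigma2=self.error_ms,
            df=self.error_df,
            n_env=self.layout.n_env,
            n_blocks=self.layout.n_blocks,
        )


def fit_anova(plots) -> AnovaTable:
    """Two-factor (genotype, environment) ANOVA with nested blocks.

    Sequential sums of squares come from an ordinary least-squares fit of
    the full fixed-effects parameterization; on a balanced layout they equal
    the classical partition.  Requires at least two environments, blocks and
    materials.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = as_plot_frame(plots)
    lay = _layout(df)
    if lay.n_env < 2 or lay.n_materials < 2 or lay.n_blocks < 2:
        raise ValueError("need >=2 environments, blocks and materials")

    df = df.assign(
        env=df["env"].astype(str),
        block=df["block"].astype(str),
        material=df["material"].astype(str),
    )
    model = smf.ols(
        "hd ~ C(env) + C(env):C(block) + C(material) + C(env):C(material)",
        data=df,
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual F warnings in the raw table
        raw = anova_lm(model, typ=1)
    rename = {
        "C(env)": "environments",
        "C(env):C(block)": "blocks_within_env",
        "C(material)": "genotypes",
        "C(env):C(material)": "GxE",
        "Residual": "error",
    }
    tab = raw.rename(index=rename)[["df", "sum_sq"]].copy()
    tab["df"] = tab["df"].astype(int)
    tab = tab[tab["df"] > 0]
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]

    n_e, b, m = lay.n_env, lay.n_blocks, lay.n_materials
    ems = pd.DataFrame(
        {
            "sigma2_e": 1.0,
            "sigma2_B": [float(m), float(m), 0.0, 0.0, 0.0],
            "sigma2_GE": [float(b), 0.0, float(b), float(b), 0.0],
            "sigma2_G": [0.0, 0.0, float(n_e * b), 0.0, 0.0],
        },
        index=["environments", "blocks_within_env", "genotypes", "GxE", "error"],
    )
    ems = ems.reindex(tab.index)

    denom = {
        "genotypes": "GxE",
        "GxE": "error",
        "blocks_within_env": "error",
        "environments": "blocks_within_env",
    }
    F = {}
    p = {}
    for src, den in denom.items():
        if src not in tab.index or den not in tab.index:
            continue
        ms_n, ms_d = tab.loc[src, "mean_sq"], tab.loc[den, "mean_sq"]
        if ms_d > 0:
            F[src] = ms_n / ms_d
            p[src] = float(
                stats.f.sf(F[src], tab.loc[src, "df"], tab.loc[den, "df"])
            )
        elif ms_n > 0:
            F[src] = np.inf
            p[src] = 0.0
        else:
            F[src] = np.nan
            p[src] = np.nan
    tab["F"] = pd.Series(F)
    tab["p"] = pd.Series(p)
    return AnovaTable(table=tab, ems=ems, layout=lay)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_GE: float
    sigma2_B: float
    sigma2_e: float
    method: str = "MINQUE1"
    raw: Dict[str, float] = field(default_factory=dict)
    truncated: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, float]:
        return {
            "G": self.sigma2_G,
            "GE": self.sigma2_GE,
            "B": self.sigma2_B,
            "e": self.sigma2_e,
        }

    @property
    def total(self) -> float:
        return self.sigma2_G + self.sigma2_GE + self.sigma2_B + self.sigma2_e


def _truncate(est: Dict[str, float], method: str) -> VarianceComponents:
    scale = max(abs(v) for v in est.values()) or 1.0
    truncated = [k for k, v in est.items() if v < -1e-10 * scale]
    if truncated:
        warnings.warn(
            f"negative variance estimates truncated to 0: {truncated}",
            stacklevel=3,
        )
    clipped = {k: max(v, 0.0) for k, v in est.items()}
    return VarianceComponents(
        sigma2_G=clipped["G"],
        sigma2_GE=clipped["GE"],
        sigma2_B=clipped["B"],
        sigma2_e=clipped["e"],
        method=method,
        raw=dict(est),
        truncated=truncated,
    )


def _design(df: pd.DataFrame, lay: Layout):
    env = pd.Categorical(df["env"].astype(str), categories=lay.environments)
    mat = pd.Categorical(df["material"].astype(str), categories=lay.materials)
    env_codes = env.codes.astype(np.int64)
    mat_codes = mat.codes.astype(np.int64)
    n = len(df)
    X = np.ones((n, lay.n_env))
    X[:, 1:] = np.eye(lay.n_env)[env_codes][:, 1:]  # intercept + env dummies
    Z_G = np.eye(lay.n_materials)[mat_codes]
    ge_codes = env_codes * lay.n_materials + mat_codes
    Z_GE = np.eye(lay.n_env * lay.n_materials)[ge_codes]
    block_labels = [
        f"{e}:{b}" for e in lay.environments for b in lay.blocks[e]
    ]
    block_index = {lab: i for i, lab in enumerate(block_labels)}
    codes = [
        block_index[f"{e}:{b}"]
        for e, b in zip(df["env"].astype(str), df["block"].astype(str))
    ]
    Z_B = np.eye(len(block_labels))[codes]
    y = df["hd"].to_numpy(dtype=float)
    return y, X, {"G": Z_G, "GE": Z_GE, "B": Z_B}


def estimate_vc_minque(
    plots, priors: Optional[Dict[str, float]] = None
) -> VarianceComponents:
    """MINQUE(1) variance components for (G, GE, B, e).

    Solves the MINQUE normal equations ``tr(Q V_i Q V_j) theta_j =
    y' Q V_i Q y`` with ``V`` built from the prior values (all 1 by
    default) and the fixed effects (mu, E) projected out.  A single pass is
    performed, matching the all-priors-one convention; negative solutions
    are truncated to zero with a warning.
    """
    df = as_plot_frame(plots)
    lay = _layout(df)
    pri = {"G": 1.0, "GE": 1.0, "B": 1.0, "e": 1.0}
    if priors:
        pri.update(priors)
    if any(v <= 0 for v in pri.values()):
        raise ValueError("priors must be strictly positive")

    y, X, Z = _design(df, lay)
    n = len(y)
    V0 = pri["e"] * np.eye(n)
    for name, Zi in Z.items():
        V0 += pri[name] * (Zi @ Zi.T)
    Vinv = np.linalg.inv(V0)
    VX = Vinv @ X
    Q = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
    Qy = Q @ y

    names = list(COMPONENTS)
    T = {name: Z[name].T @ Q for name in ("G", "GE", "B")}
    T["e"] = Q
    u = np.array(
        [
            float(np.sum((Z[nm].T @ Qy) ** 2)) if nm != "e" else float(Qy @ Qy)
            for nm in names
        ]
    )
    S = np.zeros((4, 4))
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j < i:
                S[i, j] = S[j, i]
                continue
            if nj == "e":
                S[i, j] = float(np.sum(T[ni] ** 2))
            else:
                S[i, j] = float(np.sum((T[ni] @ Z[nj]) ** 2))
    if np.linalg.cond(S) > 1e12:
        w, v = np.linalg.eigh(S)
        confounded = [
            names[k] for k in np.argsort(np.abs(v[:, 0]))[::-1][:2]
        ]
        raise ValueError(
            "singular MINQUE coefficient matrix; components "
            f"{confounded} are confounded in this layout"
        )
    theta = np.linalg.solve(S, u)
    return _truncate(dict(zip(names, map(float, theta))), "MINQUE1")


def anova_ems_components(anova: AnovaTable) -> VarianceComponents:
    """Method-of-moments components from the EMS equivalences.

    On a balanced layout: sigma2_e = MS_error, sigma2_GE = (MS_GxE -
    MS_error)/b, sigma2_G = (MS_G - MS_GxE)/(n_env*b), sigma2_B = (MS_B -
    MS_error)/m.
    """
    tab = anova.table
    lay = anova.layout
    n_e, b, m = lay.n_env, lay.n_blocks, lay.n_materials
    ms = tab["mean_sq"]
    est = {
        "e": float(ms["error"]),
        "GE": float((ms["GxE"] - ms["error"]) / b),
        "G": float((ms["genotypes"] - ms["GxE"]) / (n_e * b)),
        "B": float((ms["blocks_within_env"] - ms["error"]) / m)
        if "blocks_within_env" in ms
        else 0.0,
    }
    return _truncate(est, "ANOVA-EMS")


# ---------------------------------------------------------------------------
# prediction of random effects
# ---------------------------------------------------------------------------


@dataclass
class RandomEffectPredictions:
    """Predicted genotypic effects and G-by-E deviations.

    ``G`` is indexed by material; ``GE`` is environments x materials.  Both
    are centered: G sums to ~0 over materials and GE to ~0 over
    environments within each material (the per-material mean of the raw GE
    solutions is reallocated into G).
    """

    G: pd.Series
    GE: pd.DataFrame
    B: pd.Series
    method: str = "blup"


def predict_blup(plots, vc: VarianceComponents) -> RandomEffectPredictions:
    """BLUP of G, GE and B from Henderson's mixed-model equations.

    Variance ratios come from ``vc``; components estimated at zero drop out
    (their predictions are exactly zero).  With all random variances zero
    every prediction is zero.  A vanishing error variance is floored at a
    tiny multiple of the total variance so the equations remain solvable;
    in that limit the predictions converge to the unshrunken least-squares
    values.
    """
    df = as_plot_frame(plots)
    lay = _layout(df)
    y, X, Z = _design(df, lay)

    active = [nm for nm in ("G", "GE", "B") if vc.as_dict()[nm] > 0]
    block_labels = [f"{e}:{b}" for e in lay.environments for b in lay.blocks[e]]
    zeros_G = pd.Series(0.0, index=lay.materials)
    zeros_GE = pd.DataFrame(
        0.0, index=lay.environments, columns=lay.materials
    )
    zeros_B = pd.Series(0.0, index=block_labels)
    if not active:
        warnings.warn("all random variances are zero; predictions are zero")
        return RandomEffectPredictions(zeros_G, zeros_GE, zeros_B)

    s2e = vc.sigma2_e
    if s2e <= 0:
        s2e = max(vc.total, 1.0) * 1e-12
    Zfull = np.hstack([Z[nm] for nm in active])
    q = [Z[nm].shape[1] for nm in active]
    lam = np.concatenate(
        [np.full(qi, s2e / vc.as_dict()[nm]) for nm, qi in zip(active, q)]
    )
    XtX = X.T @ X
    XtZ = X.T @ Zfull
    ZtZ = Zfull.T @ Zfull + np.diag(lam)
    rhs = np.concatenate([X.T @ y, Zfull.T @ y])
    C = np.block([[XtX, XtZ], [XtZ.T, ZtZ]])
    sol = np.linalg.solve(C, rhs)
    u = sol[X.shape[1] :]

    parts = {}
    off = 0
    for nm, qi in zip(active, q):
        parts[nm] = u[off : off + qi]
        off += qi

    G = zeros_G.copy()
    GE = zeros_GE.copy()
    B = zeros_B.copy()
    if "G" in parts:
        G[:] = parts["G"]
    if "GE" in parts:
        GE[:] = parts["GE"].reshape(lay.n_env, lay.n_materials)
    if "B" in parts:
        B[:] = parts["B"]
    # center GE within material; the removed mean is genotype main-effect
    # signal, so it moves into G — unless G has zero variance, in which case
    # the model admits no genotype main effects and the mean is discarded
    ge_mean = GE.mean(axis=0)
    GE = GE - ge_mean
    if vc.sigma2_G > 0:
        G = G + ge_mean
    G = G - G.mean()
    return RandomEffectPredictions(G=G, GE=GE, B=B, method="blup")


def predict_ls(plots) -> RandomEffectPredictions:
    """Unshrunken least-squares predictions from cell means.

    G is the centered material mean, GE the interaction deviation
    ``ybar_hj - ybar_h - ybar_j + ybar``; these are the inputs under which
    downstream contrast t-tests are exact.
    """
    df = as_plot_frame(plots)
    lay = _layout(df)
    grand = df["hd"].mean()
    mat_means = df.groupby("material", observed=True)["hd"].mean()
    env_means = df.groupby("env", observed=True)["hd"].mean()
    cell = df.groupby(["env", "material"], observed=True)["hd"].mean().unstack()
    cell = cell.reindex(index=lay.environments, columns=lay.materials)
    G = (mat_means - grand).reindex(lay.materials)
    GE = cell.sub(env_means.reindex(lay.environments), axis=0).sub(
        mat_means.reindex(lay.materials), axis=1
    ) + grand
    blk = df.groupby(["env", "block"], observed=True)["hd"].mean()
    B = pd.Series(
        {
            f"{e}:{b}": blk[(e, b)] - env_means[e]
            for e in lay.environments
            for b in lay.blocks[e]
        }
    )
    return RandomEffectPredictions(G=G, GE=GE, B=B, method="ls")


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeritabilityEstimate:
    general: float
    peculiar: float


def heritability(
    vc: VarianceComponents,
    layout: Optional[Layout] = None,
    basis: str = "plot",
) -> HeritabilityEstimate:
    """General (G share) and peculiar (GE share) heritability.

    On the default plot basis the phenotypic variance is the plain sum of
    the four components.  On the entry-mean basis (``basis="mean"``) the
    interaction, block and error variances are divided by their replication,
    which requires the trial layout.
    """
    if basis == "plot":
        denom = vc.total
    elif basis == "mean":
        if layout is None:
            raise ValueError("entry-mean basis requires the trial layout")
        n_e, b = layout.n_env, layout.n_blocks
        denom = (
            vc.sigma2_G
            + vc.sigma2_GE / n_e
            + vc.sigma2_B / (n_e * b)
            + vc.sigma2_e / (n_e * b)
        )
    else:
        raise ValueError(f"unknown heritability basis {basis!r}")
    if denom <= 0:
        raise ValueError("phenotypic variance is zero; heritability undefined")
    g = vc.sigma2_G if basis == "plot" else vc.sigma2_G
    ge = vc.sigma2_GE if basis == "plot" else vc.sigma2_GE / layout.n_env
    return HeritabilityEstimate(general=g / denom, peculiar=ge / denom)


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    anova: AnovaTable
    vc: VarianceComponents
    blup: RandomEffectPredictions
    ls: RandomEffectPredictions
    err: ErrorContext
    heritability: HeritabilityEstimate


def fit_mixed_model(
    plots,
    priors: Optional[Dict[str, float]] = None,
    h2_basis: str = "plot",
) -> FitResult:
    """ANOVA, MINQUE(1) components, BLUP and LS predictions in one pass."""
    df = as_plot_frame(plots)
    anova = fit_anova(df)
    vc = estimate_vc_minque(df, priors=priors)
    blup = predict_blup(df, vc)
    ls = predict_ls(df)
    h2 = heritability(vc, layout=anova.layout, basis=h2_basis)
    return FitResult(
        anova=anova,
        vc=vc,
        blup=blup,
        ls=ls,
        err=anova.error_context(),
        heritability=h2,
    )
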