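"""Signed linear kinetic model of a curated regulatory subnetwork.

Each node (gene, or lncRNA acting as a regulator) follows

    dx_i/dt = beta_i + sum_j s_ji * w_ji * x_j - delta_i * x_i,   x_i >= 0

with basal production ``beta_i >= 0``, first-order decay ``delta_i > 0``,
nonnegative edge weights ``w_ji`` and fixed regulatory signs
``s_ji in {+1, -1}`` taken from curation.  The form is the minimal signed
kinetic model that supports virtual deletion ("knockout") experiments:
clamping a node to zero and comparing mutant to wild-type trajectories,
e.g. removing either of two repressors of a target raises the target's
steady state, the stronger repressor more.

Fitting follows the statsmodels convention: a :class:`RegulatoryODE` model
object is built from a time-course table and a signed edge list, and
``fit()`` returns a :class:`RegulatoryODEResults` carrying the estimates,
per-node residuals and a ``summary()`` table; simulation and knockouts hang
off the results (or off a bare parameter set via the module functions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls


@dataclass
class RegulatoryODEModel:
    """Parameter set of the signed linear kinetic model.

    ``edges`` maps (source, target) -> (weight, sign); ``basal`` and
    ``decay`` map node -> parameter.  With all weights zero the model
    decouples and each node relaxes to the steady state beta/delta.
    """

    nodes: list[str]
    basal: dict[str, float]
    decay: dict[str, float]
    edges: dict[tuple[str, str], tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.nodes:
            if self.basal.get(n, 0.0) < 0:
                raise ValueError(f"basal rate of {n} must be >= 0")
            if self.decay.get(n, 1.0) <= 0:
                raise ValueError(f"decay rate of {n} must be > 0")
        for (s, t), (w, sg) in self.edges.items():
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge {s}->{t} references unknown node")
            if w < 0:
                raise ValueError(f"weight of {s}->{t} must be >= 0")
            if sg not in (1, -1):
                raise ValueError(f"sign of {s}->{t} must be +1 or -1")

    def parents(self, node: str) -> list[tuple[str, float, int]]:
        return [(s, w, sg) for (s, t), (w, sg) in self.edges.items() if t == node]

    def rhs(self, x: np.ndarray, knocked: frozenset[str] = frozenset()) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.nodes)}
        dx = np.empty(len(self.nodes))
        for i, n in enumerate(self.nodes):
            if n in knocked:
                dx[i] = 0.0
                continue
            v = self.basal.get(n, 0.0) - self.decay.get(n, 1.0) * x[i]
            for s, w, sg in self.parents(n):
                v += sg * w * x[idx[s]]
            dx[i] = v
        return dx

    def steady_state(self) -> dict[str, float]:
        """Closed-form linear steady state (ignores the x >= 0 clamp)."""
        n = len(self.nodes)
        idx = {m: i for i, m in enumerate(self.nodes)}
        a = np.zeros((n, n))
        b = np.zeros(n)
        for i, m in enumerate(self.nodes):
            a[i, i] = -self.decay.get(m, 1.0)
            b[i] = -self.basal.get(m, 0.0)
            for s, w, sg in self.parents(m):
                a[i, idx[s]] += sg * w
        x = np.linalg.solve(a, b)
        return dict(zip(self.nodes, x))


@dataclass
class KnockoutResult:
    """Wild-type vs virtual-deletion trajectories and steady-state shifts."""

    knocked: list[str]
    wild_type: pd.DataFrame     # time x node
    mutant: pd.DataFrame
    steady_state_delta: pd.Series  # mutant - wild-type at the last time point

    def fold_change(self, node: str) -> float:
        wt = self.wild_type[node].iloc[-1]
        return float(self.mutant[node].iloc[-1] / wt) if wt else np.inf


def simulate(model: RegulatoryODEModel, x0: Mapping[str, float],
             t_grid: Sequence[float], dt: float = 0.01,
             knocked: Iterable[str] = ()) -> pd.DataFrame:
    """Fixed-step RK4 integration with post-step clamping at zero.

    Returns a time x node DataFrame sampled at ``t_grid``.  Knocked nodes
    are held at exactly zero throughout.
    """
    t_grid = np.asarray(list(t_grid), dtype=float)
    if len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    knocked = frozenset(knocked)
    x = np.array([0.0 if n in knocked else float(x0.get(n, 0.0)) for n in model.nodes])
    if np.any(x < 0):
        raise ValueError("initial state must be nonnegative")
    ko_mask = np.array([n in knocked for n in model.nodes])

    out = np.empty((len(t_grid), len(model.nodes)))
    t = t_grid[0]
    out[0] = x
    for k in range(1, len(t_grid)):
        target = t_grid[k]
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = model.rhs(x, knocked)
            k2 = model.rhs(x + 0.5 * h * k1, knocked)
            k3 = model.rhs(x + 0.5 * h * k2, knocked)
            k4 = model.rhs(x + h * k3, knocked)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            np.maximum(x, 0.0, out=x)
            x[ko_mask] = 0.0
            t += h
        out[k] = x
        t = target
    return pd.DataFrame(out, index=t_grid, columns=model.nodes)


def virtual_knockout(model: RegulatoryODEModel, nodes_to_knock: Iterable[str],
                     x0: Mapping[str, float], t_grid: Sequence[float],
                     dt: float = 0.01) -> KnockoutResult:
    """Simulate a deletion strain by clamping the knocked nodes to zero."""
    knocked = list(nodes_to_knock)
    unknown = set(knocked) - set(model.nodes)
    if unknown:
        raise ValueError(f"unknown nodes: {sorted(unknown)}")
    if set(knocked) >= set(model.nodes):
        raise ValueError("cannot knock out every node")
    wt = simulate(model, x0, t_grid, dt=dt)
    mut = simulate(model, x0, t_grid, dt=dt, knocked=knocked)
    delta = mut.iloc[-1] - wt.iloc[-1]
    return KnockoutResult(knocked, wt, mut, delta)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class RegulatoryODE:
    """Gradient-matching estimator for the signed kinetic model.

    Parameters
    ----------
    timecourse
        time x node DataFrame of (nonnegative) expression levels; the index
        holds sampling times in hours.
    edges
        DataFrame with columns ``source, target, sign`` (+1 activation,
        -1 repression) from curation.
    """

    def __init__(self, timecourse: pd.DataFrame, edges: pd.DataFrame):
        if len(timecourse) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(timecourse.index.to_numpy(dtype=float)) <= 0):
            raise ValueError("time index must be strictly increasing")
        if missing := {"source", "target", "sign"} - set(edges.columns):
            raise ValueError(f"edge table missing columns {sorted(missing)}")
        unknown = (set(edges["source"]) | set(edges["target"])) - set(timecourse.columns)
        if unknown:
            raise ValueError(f"edge nodes absent from time course: {sorted(unknown)}")
        if timecourse.std().max() == 0:
            raise ValueError("all series constant: singular design, cannot fit")
        self.timecourse = timecourse
        self.edges = edges.reset_index(drop=True)

    def fit(self) -> "RegulatoryODEResults":
        """Per-node nonnegativity-constrained least squares on finite-difference derivatives."""
        t = self.timecourse.index.to_numpy(dtype=float)
        x = self.timecourse.to_numpy(dtype=float)
        dxdt = np.gradient(x, t, axis=0)
        # boundary finite differences are only first-order: regress on the
        # interior (central-difference) points when enough rows remain
        rows = slice(1, -1) if len(t) >= 5 else slice(None)
        nodes = list(self.timecourse.columns)
        idx = {n: i for i, n in enumerate(nodes)}

        basal, decay, weights = {}, {}, {}
        residuals = {}
        for n in nodes:
            parents = [(r.source, int(r.sign)) for r in self.edges.itertuples(index=False)
                       if r.target == n]
            # design: dx = beta * 1 + sum_j sign_j * w_j * x_j - delta * x_i
            cols = [np.ones(len(t))]
            cols += [sg * x[:, idx[p]] for p, sg in parents]
            cols += [-x[:, idx[n]]]
            a = np.column_stack(cols)
            theta, rnorm = nnls(a[rows], dxdt[rows, idx[n]])
            basal[n] = float(theta[0])
            decay[n] = float(max(theta[-1], 1e-12))
            for (p, sg), w in zip(parents, theta[1:-1]):
                weights[(p, n)] = (float(w), sg)
            residuals[n] = float(rnorm)
        model = RegulatoryODEModel(nodes, basal, decay, weights)
        return RegulatoryODEResults(self, model, pd.Series(residuals))


class RegulatoryODEResults:
    """Fitted parameters, fit diagnostics, and simulation entry points."""

    def __init__(self, model_spec: RegulatoryODE, params: RegulatoryODEModel,
                 resid_norm: pd.Series):
        self.model_spec = model_spec
        self.params = params
        self.resid_norm = resid_norm

    def simulate(self, x0: Mapping[str, float] | None = None,
                 t_grid: Sequence[float] | None = None, dt: float = 0.01) -> pd.DataFrame:
        x0 = x0 if x0 is not None else self.model_spec.timecourse.iloc[0].to_dict()
        if t_grid is None:
            t0 = float(self.model_spec.timecourse.index[0])
            t_grid = np.linspace(t0, t0 + 8.0, 81)
        return simulate(self.params, x0, t_grid, dt=dt)

    def knockout(self, nodes_to_knock: Iterable[str],
                 x0: Mapping[str, float] | None = None,
                 t_grid: Sequence[float] | None = None, dt: float = 0.01) -> KnockoutResult:
        x0 = x0 if x0 is not None else self.model_spec.timecourse.iloc[0].to_dict()
        if t_grid is None:
            t0 = float(self.model_spec.timecourse.index[0])
            t_grid = np.linspace(t0, t0 + 8.0, 81)
        return virtual_knockout(self.params, nodes_to_knock, x0, t_grid, dt=dt)

    def summary(self) -> str:
        lines = ["Signed regulatory ODE (gradient matching, NNLS)",
                 f"nodes: {len(self.params.nodes)}   edges: {len(self.params.edges)}",
                 "",
                 f"{'node':<14}{'basal':>10}{'decay':>10}{'resid':>12}"]
        for n in self.params.nodes:
            lines.append(f"{n:<14}{self.params.basal[n]:>10.4f}"
                         f"{self.params.decay[n]:>10.4f}{self.resid_norm[n]:>12.4g}")
        lines.append("")
        lines.append(f"{'edge':<22}{'sign':>6}{'weight':>10}")
        for (s, t), (w, sg) in sorted(self.params.edges.items()):
            lines.append(f"{s + ' -> ' + t:<22}{sg:>+6d}{w:>10.4f}")
        return "\n".join(lines)

    def plot_trajectories(self, result: KnockoutResult | None = None, ax=None):
        """Overlay observed points and simulated (optionally knockout) curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.model_spec.timecourse
        sim = result.mutant if result is not None else self.simulate()
        for n in self.params.nodes:
            ax.plot(sim.index, sim[n], label=n)
            ax.plot(obs.index, obs[n], "o", ms=3)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("expression")
        ax.legend(fontsize="small")
        return ax


def fit_ode(edges: pd.DataFrame, timecourse: pd.DataFrame) -> RegulatoryODEResults:
    """Convenience wrapper: build the model from a signed edge table and fit."""
    return RegulatoryODE(timecourse, edges).fit()


def two_repressor_motif(w_strong: float = 1.0, w_weak: float = 0.3,
                        beta_target: float = 2.0) -> RegulatoryODEModel:
    """Target repressed by a strong and a weak regulator.

    Mirrors the curated ADH2-type motif in which two repressors act on one
    target; knocking out either raises the target, the strong one more.
    """
    nodes = ["target", "rep_strong", "rep_weak"]
    basal = {"target": beta_target, "rep_strong": 1.0, "rep_weak": 1.0}
    decay = {n: 1.0 for n in nodes}
    edges = {("rep_strong", "target"): (w_strong, -1),
             ("rep_weak", "target"): (w_weak, -1)}
    return RegulatoryODEModel(nodes, basal, decay, edges)
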