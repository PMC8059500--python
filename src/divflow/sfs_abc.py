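"""Joint-SFS construction and rejection-ABC model selection.

The observed joint site-frequency spectrum is built from a filtered,
LD-pruned, fourfold-degenerate-restricted variant table, either by seeded
subsampling of k individuals per species (sites with missing calls in the
subsample are dropped) or by hypergeometric down-projection of each site's
allele counts to 2k alleles per species.

Model choice among divergence scenarios uses plain rejection ABC: simulate
a reference table of joint spectra under each scenario with parameters
drawn from priors, rank all pooled simulations by Euclidean distance
between mass-normalized spectra, accept the closest fraction, and report
each scenario's share of the accepted set.  The distance excludes the two
structurally empty corner cells, and mass normalization makes it invariant
to the number of segregating sites a simulation happens to produce.

The inference surface follows the model/results idiom:
``ABCModelSelection(obs, labels, priors, cfg).fit(...)`` returns an
:class:`ABCResults` carrying acceptance proportions, the accepted draws,
per-parameter posterior summaries and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .coalescent import SimConfig, make_model, simulate_joint_sfs
from .sfs import JointSFS
from .variants import VariantTable

__all__ = [
    "PriorSpec",
    "ABCModelSelection",
    "ABCResults",
    "observed_joint_sfs",
    "simulate_reference_table",
    "abc_model_select",
    "abc_posterior",
]

DEFAULT_TOLERANCE = 0.005
PARAM_COLS = ["T_split", "N1", "N2", "N_anc", "m"]


@dataclass(frozen=True)
class PriorSpec:
    """Prior distributions for the demographic parameters.

    Each entry maps a parameter to ``("uniform", lo, hi)``,
    ``("loguniform", lo, hi)`` or ``("fixed", value)``.  The defaults are a
    deliberately wide, weakly informative choice: log-uniform sizes over
    1e4-1e7 diploids, uniform symmetric migration over 0-1e-4 per lineage
    per generation, and the split time fixed at 1e6 generations.
    """

    params: dict = field(default_factory=lambda: {
        "T_split": ("fixed", 1_000_000.0),
        "N1": ("loguniform", 1e4, 1e7),
        "N2": ("loguniform", 1e4, 1e7),
        "N_anc": ("loguniform", 1e4, 1e7),
        "m": ("uniform", 0.0, 1e-4),
    })

    def __post_init__(self) -> None:
        for name, spec in self.params.items():
            kind = spec[0]
            if kind == "fixed":
                continue
            if kind not in ("uniform", "loguniform"):
                raise ValueError(f"unknown prior family {kind!r} for {name}")
            lo, hi = spec[1], spec[2]
            if not (0 <= lo < hi) or (kind == "loguniform" and lo <= 0):
                raise ValueError(f"bad bounds for {name}: {spec}")

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        draw = {}
        for name, spec in self.params.items():
            kind = spec[0]
            if kind == "fixed":
                draw[name] = float(spec[1])
            elif kind == "uniform":
                draw[name] = float(rng.uniform(spec[1], spec[2]))
            else:
                draw[name] = float(
                    np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2])))
                )
        return draw


# ---- observed SFS ------------------------------------------------------

def observed_joint_sfs(
    vt: VariantTable,
    k: int = 6,
    mode: str = "subsample",
    fold: bool = True,
    rng: np.random.Generator | None = None,
    pop1: str = "sp1",
    pop2: str = "sp2",
) -> JointSFS:
    """Observed joint SFS at ``2k`` alleles per species.

    ``subsample`` draws k individuals per species (seeded) and keeps only
    sites completely genotyped in the draw; ``projection`` spreads each
    site's mass over a ``(2k+1) x (2k+1)`` grid with exact hypergeometric
    weights, skipping sites with fewer than 2k non-missing alleles in
    either species.  Folding (default) maps each cell onto its minor-allele
    configuration.
    """
    if rng is None:
        rng = np.random.default_rng()
    idx1 = vt.pop_index(pop1)
    idx2 = vt.pop_index(pop2)
    if len(idx1) < k or len(idx2) < k:
        raise ValueError(f"need at least {k} individuals per species")
    m = 2 * k

    if mode == "subsample":
        sub1 = rng.choice(idx1, size=k, replace=False)
        sub2 = rng.choice(idx2, size=k, replace=False)
        gt1 = vt.gt[:, sub1, :]
        gt2 = vt.gt[:, sub2, :]
        complete = (gt1 >= 0).all(axis=(1, 2)) & (gt2 >= 0).all(axis=(1, 2))
        d1 = (gt1 == 1).sum(axis=(1, 2))[complete]
        d2 = (gt2 == 1).sum(axis=(1, 2))[complete]
        mat = np.zeros((m + 1, m + 1), dtype=np.int64)
        np.add.at(mat, (d1, d2), 1)
    elif mode == "projection":
        a1, t1 = vt.allele_counts(idx1)
        a2, t2 = vt.allele_counts(idx2)
        ok = (t1 >= m) & (t2 >= m)
        mat = np.zeros((m + 1, m + 1), dtype=float)
        xs = np.arange(m + 1)
        for d1, n1, d2, n2 in zip(a1[ok], t1[ok], a2[ok], t2[ok]):
            w1 = hypergeom.pmf(xs, n1, d1, m)
            w2 = hypergeom.pmf(xs, n2, d2, m)
            mat += np.outer(w1, w2)
    else:
        raise ValueError("mode must be 'subsample' or 'projection'")
    sfs = JointSFS(mat, folded=False)
    return sfs.fold() if fold else sfs


# ---- reference table and rejection ------------------------------------

def simulate_reference_table(
    models,
    priors: PriorSpec,
    n_sims_per_model: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    fold: bool = True,
) -> pd.DataFrame:
    """Simulate the pooled ABC reference table.

    ``models`` is a list of scenario labels (M1..M5) or
    ``(label, PriorSpec)`` pairs when scenarios use different priors.  Each
    row holds the scenario label, the drawn parameters, and the
    mass-normalized (corner-free) SFS vector of one simulation.
    """
    rows = []
    vec_len = None
    for entry in models:
        label, pri = entry if isinstance(entry, tuple) else (entry, priors)
        for _ in range(n_sims_per_model):
            draw = pri.sample(rng)
            model = make_model(
                label, draw["T_split"], draw["N1"], draw["N2"],
                draw["N_anc"], draw["m"],
            )
            sfs = simulate_joint_sfs(model, cfg, rng)
            if fold:
                sfs = sfs.fold()
            vec = sfs.mass_vector()
            vec_len = len(vec)
            rows.append(
                [label, bool(fold)] + [draw[p] for p in PARAM_COLS] + list(vec)
            )
    cols = (["model", "folded"] + PARAM_COLS
            + [f"sfs_{i}" for i in range(vec_len or 0)])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ABCResults:
    """Rejection-ABC model-selection results.

    ``accepted`` holds the accepted draws (scenario label, parameters,
    distance); ``proportions`` are each scenario's share of the accepted
    set and sum to one.
    """

    proportions: dict[str, float]
    n_simulated: dict[str, int]
    n_accepted: dict[str, int]
    accepted: pd.DataFrame
    tolerance: float
    max_accepted_distance: float
    seed: int | None = None

    @property
    def best_model(self) -> str:
        return max(self.proportions, key=self.proportions.get)

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(
            self.proportions.items(), key=lambda kv: kv[1], reverse=True
        )

    def posterior(self, label: str) -> pd.DataFrame:
        """Accepted-draw summaries (mean, median, 95% CI) per parameter."""
        sub = self.accepted[self.accepted["model"] == label]
        if len(sub) == 0:
            raise ValueError(f"no accepted draws for model {label!r}")
        stats = {}
        for p in PARAM_COLS:
            v = sub[p].to_numpy()
            stats[p] = {
                "mean": v.mean(),
                "median": float(np.median(v)),
                "q2.5": float(np.quantile(v, 0.025)),
                "q97.5": float(np.quantile(v, 0.975)),
                "n": len(v),
            }
        return pd.DataFrame(stats).T

    def summary(self) -> str:
        lines = [
            "Rejection-ABC model selection",
            "=" * 46,
            f"tolerance: {self.tolerance:g}   "
            f"accepted: {sum(self.n_accepted.values())} of "
            f"{sum(self.n_simulated.values())}",
            f"{'model':<8}{'simulated':>10}{'accepted':>10}{'proportion':>12}",
            "-" * 46,
        ]
        for label, prop in self.ranking():
            lines.append(
                f"{label:<8}{self.n_simulated[label]:>10}"
                f"{self.n_accepted[label]:>10}{prop:>11.1%}"
            )
        lines.append("-" * 46)
        return "\n".join(lines)


def abc_model_select(
    obs: JointSFS, ref: pd.DataFrame, tolerance: float = DEFAULT_TOLERANCE
) -> ABCResults:
    """Rank pooled simulations by distance to the observed SFS and accept
    the closest ``round(tolerance x N)`` (at least one)."""
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    sfs_cols = [c for c in ref.columns if c.startswith("sfs_")]
    obs_vec = obs.mass_vector()
    if len(sfs_cols) != len(obs_vec):
        raise ValueError("observed and reference SFS dimensions differ")
    if "folded" in ref.columns and not ref["folded"].eq(obs.folded).all():
        raise ValueError("observed and reference SFS polarization differ")
    sims = ref[sfs_cols].to_numpy(dtype=float)
    dist = np.sqrt(((sims - obs_vec[None, :]) ** 2).sum(axis=1))
    n_total = len(ref)
    n_accept = max(1, round(tolerance * n_total))
    order = np.argsort(dist, kind="stable")[:n_accept]
    acc = ref.iloc[order][["model"] + PARAM_COLS].copy()
    acc["distance"] = dist[order]
    labels = list(dict.fromkeys(ref["model"]))
    n_sim = {m: int((ref["model"] == m).sum()) for m in labels}
    n_acc = {m: int((acc["model"] == m).sum()) for m in labels}
    props = {m: n_acc[m] / n_accept for m in labels}
    return ABCResults(
        proportions=props,
        n_simulated=n_sim,
        n_accepted=n_acc,
        accepted=acc.reset_index(drop=True),
        tolerance=tolerance,
        max_accepted_distance=float(dist[order[-1]]),
    )


def abc_posterior(res: ABCResults, label: str) -> pd.DataFrame:
    """Per-parameter posterior summaries for one scenario (functional form)."""
    return res.posterior(label)


class ABCModelSelection:
    """Model object tying an observed SFS to scenarios and priors.

    Parameters
    ----------
    obs : JointSFS
        Observed spectrum (its polarization decides the reference table's).
    model_labels : list of scenario labels, default M1..M5.
    priors : PriorSpec or ``{label: PriorSpec}``.
    cfg : SimConfig
        Sample sizes must match the observed spectrum (``n1 = 2k1`` etc.).
    """

    def __init__(self, obs: JointSFS, model_labels=None,
                 priors: PriorSpec | dict | None = None,
                 cfg: SimConfig | None = None):
        self.obs = obs
        self.model_labels = list(model_labels or ["M1", "M2", "M3", "M4", "M5"])
        self.priors = priors if priors is not None else PriorSpec()
        self.cfg = cfg or SimConfig(n1=obs.n1, n2=obs.n2)
        if (self.cfg.n1, self.cfg.n2) != (obs.n1, obs.n2):
            raise ValueError("SimConfig sample sizes must match the observed SFS")

    def _model_entries(self):
        if isinstance(self.priors, dict):
            return [(m, self.priors[m]) for m in self.model_labels]
        return [(m, self.priors) for m in self.model_labels]

    def simulate_reference(self, n_sims_per_model: int,
                           rng: np.random.Generator) -> pd.DataFrame:
        return simulate_reference_table(
            self._model_entries(), PriorSpec(), n_sims_per_model, self.cfg,
            rng, fold=self.obs.folded,
        )

    def fit(
        self,
        n_sims_per_model: int = 2000,
        tolerance: float = DEFAULT_TOLERANCE,
        seed: int | None = None,
        reference: pd.DataFrame | None = None,
    ) -> ABCResults:
        """Simulate (or reuse) the reference table and run rejection."""
        if reference is None:
            rng = np.random.default_rng(seed)
            reference = self.simulate_reference(n_sims_per_model, rng)
        res = abc_model_select(self.obs, reference, tolerance)
        res.seed = seed
        return res
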