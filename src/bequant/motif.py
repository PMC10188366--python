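"""Sequence-context preference motifs by ridge regression.

Member-level editing efficiencies are transformed with a stabilised logit,
log((x + eps) / (1 + eps - x)) with eps = 0.001, and regressed on a one-hot
encoding of the bases at offsets -3..+3 (excluding 0) around the substrate
base.  An 80:20 train/test split gives a held-out Pearson correlation
(``test_r``) used as motif confidence; per-offset weights are reported after
centering to mean zero over the four bases, which removes the one-hot
identifiability degeneracy.  Separate models are fitted per substrate base
(C vs A) and outcome class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .library import DNA_BASES, LibraryMember
from .simulate import CONTEXT_OFFSETS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifConfig:
    epsilon: float = 0.001
    ridge_alpha: float = 1e-5
    train_fraction: float = 0.8
    context_offsets: tuple[int, ...] = CONTEXT_OFFSETS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be a small positive constant")
        if self.ridge_alpha <= 0:
            raise ValueError("ridge_alpha must be > 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if 0 in self.context_offsets:
            raise ValueError("context offsets exclude 0 (the edited base itself)")


def stabilized_logit(x, epsilon: float = 0.001):
    """log((x + eps) / (1 + eps - x)); finite at 0 and 1, antisymmetric.

    Natural log; strictly increasing on [0, 1] with f(0.5) = 0 exactly and
    f(1 - x) = -f(x).
    """
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("efficiencies must lie in [0, 1]")
    # (1 - x) + eps rather than (1 + eps) - x: algebraically identical but
    # bitwise symmetric, so f(0.5) == 0.0 exactly and f(1-x) == -f(x)
    out = np.log((arr + epsilon) / ((1 - arr) + epsilon))
    return float(out) if np.isscalar(x) else out


def encode_context(
    member: LibraryMember,
    target_pos: int | None = None,
    offsets: tuple[int, ...] = CONTEXT_OFFSETS,
) -> np.ndarray:
    """One-hot feature vector: 4 indicators per context offset."""
    if target_pos is None:
        target_pos = member.target_base_pos
    ctx = member.context(target_pos, offsets)
    return encode_context_string("".join(ctx[o] for o in offsets))


def encode_context_string(context: str) -> np.ndarray:
    vec = np.zeros(4 * len(context))
    for i, base in enumerate(context):
        vec[4 * i + DNA_BASES.index(base)] = 1.0
    return vec


@dataclass
class MotifResults:
    """Fitted context motif: centered weights, intercept and held-out R."""

    config: MotifConfig
    intercept: float
    #: rows = offsets, columns = A, C, G, T; each row sums to zero
    weights: pd.DataFrame
    test_r: float
    n_train: int
    n_test: int

    @property
    def opacity(self) -> float:
        """Logo opacity: held-out correlation clipped at zero."""
        return max(self.test_r, 0.0)

    def matrix(self) -> pd.DataFrame:
        return self.weights.copy()

    def predict(self, contexts: Sequence[str]) -> np.ndarray:
        """Predicted stabilised-logit efficiency for context strings."""
        X = np.stack([encode_context_string(c) for c in contexts])
        w = self.weights.to_numpy().ravel()
        return self.intercept + X @ w

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "offsets": [int(o) for o in self.weights.index],
            "bases": list(self.weights.columns),
            "weights": self.weights.to_numpy().tolist(),
            "test_r": self.test_r,
            "opacity": self.opacity,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=False)

    @classmethod
    def from_json(cls, path, config: MotifConfig | None = None) -> "MotifResults":
        with open(path) as fh:
            d = json.load(fh)
        weights = pd.DataFrame(
            d["weights"], index=d["offsets"], columns=d["bases"]
        )
        return cls(
            config=config or MotifConfig(),
            intercept=d["intercept"],
            weights=weights,
            test_r=d["test_r"],
            n_train=d["n_train"],
            n_test=d["n_test"],
        )

    def plot(self, ax=None):
        """Bar-matrix rendering of the motif; opacity encodes held-out R.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        offsets = list(self.weights.index)
        x = np.arange(len(offsets))
        width = 0.2
        for i, base in enumerate(self.weights.columns):
            ax.bar(
                x + (i - 1.5) * width,
                self.weights[base],
                width,
                label=base,
                alpha=max(self.opacity, 0.15),
            )
        ax.axhline(0, color="black", lw=0.5)
        ax.set_xticks(x, offsets)
        ax.set_xlabel("offset from substrate base")
        ax.set_ylabel("centered log-odds weight")
        ax.legend(title=f"R = {self.test_r:.2f}", fontsize=8)
        return ax

    def summary(self) -> str:
        lines = [
            "Context motif (ridge on stabilised-logit efficiency)",
            f"  alpha={self.config.ridge_alpha:g}  eps={self.config.epsilon:g}  "
            f"train/test={self.n_train}/{self.n_test}",
            f"  held-out Pearson R = {self.test_r:.3f}  (opacity {self.opacity:.3f})",
            "",
            self.weights.round(3).to_string(),
        ]
        return "\n".join(lines)


class ContextMotif:
    """Context-preference model for one substrate and outcome class.

    Statsmodels-style: construct from data, call :meth:`fit` for results.

    Parameters
    ----------
    contexts
        Context strings (bases at the configured offsets, 5' to 3').
    efficiencies
        Member-level editing efficiencies in [0, 1], aligned with contexts.
    config
        Transform, ridge and split settings.
    """

    def __init__(
        self,
        contexts: Sequence[str],
        efficiencies: Sequence[float],
        config: MotifConfig | None = None,
    ) -> None:
        self.config = config or MotifConfig()
        if len(contexts) != len(efficiencies):
            raise ValueError("contexts and efficiencies must be aligned")
        if len(contexts) < 50:
            raise ValueError("need >= 50 observations to fit a motif")
        width = len(self.config.context_offsets)
        for c in contexts:
            if len(c) != width or set(c) - set(DNA_BASES):
                raise ValueError(f"bad context string {c!r}")
        self.contexts = list(contexts)
        self.efficiencies = np.asarray(efficiencies, dtype=float)
        if np.any(~np.isfinite(self.efficiencies)):
            raise ValueError("efficiencies must be finite")

    @classmethod
    def from_members(
        cls,
        members: Sequence[LibraryMember],
        efficiencies: Sequence[float],
        target_base: str = "C",
        config: MotifConfig | None = None,
    ) -> "ContextMotif":
        """Build from library members with the given substrate target base."""
        cfg = config or MotifConfig()
        ctx, eff = [], []
        for m, e in zip(members, efficiencies, strict=True):
            if m.target_base != target_base or not np.isfinite(e):
                continue
            d = m.context(m.target_base_pos, cfg.context_offsets)
            ctx.append("".join(d[o] for o in cfg.context_offsets))
            eff.append(e)
        return cls(ctx, eff, cfg)

    def fit(self) -> MotifResults:
        cfg = self.config
        y = stabilized_logit(self.efficiencies, cfg.epsilon)
        X = np.stack([encode_context_string(c) for c in self.contexts])
        rng = np.random.default_rng(cfg.rng_seed)
        order = rng.permutation(len(y))
        n_train = int(round(cfg.train_fraction * len(y)))
        train, test = order[:n_train], order[n_train:]

        if np.ptp(y[train]) == 0:
            logger.warning("zero-variance targets; motif weights set to 0")
            weights = np.zeros(X.shape[1])
            intercept = float(y[train][0]) if n_train else 0.0
            test_r = 0.0
        else:
            model = Ridge(alpha=cfg.ridge_alpha, fit_intercept=True)
            model.fit(X[train], y[train])
            weights = model.coef_
            intercept = float(model.intercept_)
            pred = model.predict(X[test])
            if np.ptp(pred) == 0 or np.ptp(y[test]) == 0:
                test_r = 0.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    test_r = float(np.corrcoef(pred, y[test])[0, 1])

        # center per offset; fold the removed means into the intercept
        mat = weights.reshape(len(cfg.context_offsets), 4)
        row_means = mat.mean(axis=1, keepdims=True)
        centered = mat - row_means
        intercept += float(row_means.sum())
        wdf = pd.DataFrame(
            centered, index=list(cfg.context_offsets), columns=list(DNA_BASES)
        )
        return MotifResults(
            config=cfg,
            intercept=intercept,
            weights=wdf,
            test_r=test_r,
            n_train=len(train),
            n_test=len(test),
        )


def fit_motif(
    contexts: Sequence[str],
    efficiencies: Sequence[float],
    config: MotifConfig | None = None,
) -> MotifResults:
    """Functional wrapper: ``ContextMotif(contexts, efficiencies).fit()``."""
    return ContextMotif(contexts, efficiencies, config).fit()


def member_efficiencies(
    pooled: pd.DataFrame,
    members: Sequence[LibraryMember],
    mutation: tuple[str, str] = ("C", "T"),
) -> tuple[list[LibraryMember], np.ndarray]:
    """Member-level pooled efficiency of ``mutation`` at the designed target.

    Returns the members (with the matching substrate base) and their pooled
    efficiencies at ``target_base_pos``, skipping members without coverage.
    """
    ref, alt = mutation
    sel = pooled[(pooled["ref_base"] == ref) & (pooled["alt_base"] == alt)]
    by_member = {
        (mid, pos): eff
        for mid, pos, eff in zip(sel["member_id"], sel["position"], sel["efficiency"])
    }
    out_members, out_eff = [], []
    for m in members:
        if m.target_base != ref:
            continue
        eff = by_member.get((m.member_id, m.target_base_pos))
        if eff is None or not np.isfinite(eff):
            continue
        out_members.append(m)
        out_eff.append(float(eff))
    return out_members, np.asarray(out_eff)
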