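"""Model specifications and the degrees-of-freedom ledger.

Sample statistics in the two-level limited-information setting are the
``sum_m (K_m - 1)`` thresholds, the ``M(M-1)/2`` within-level correlations
(the within diagonal is fixed at 1 by the delta convention) and the
``M(M+1)/2`` between-level (co)variances.  Free parameters are counted per
specification; the difference is the test degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelSpec", "count_df", "CONSTRAINT_SETS"]

# documented constraint combinations
CONSTRAINT_SETS = [
    frozenset(),
    frozenset({"no_between_residuals"}),
    frozenset({"cross_level_equal_loadings", "no_between_residuals"}),
    frozenset({"loadings_fixed_one", "equal_within_residuals", "no_between_residuals"}),
]


@dataclass
class ModelSpec:
    """Two-level measurement model specification.

    ``mode`` is ``"efa"`` (loadings free with rotational identification,
    unit factor variances) or ``"cfa"`` (binary loading patterns
    ``pattern_W`` / ``pattern_B``).  ``constraints`` selects the documented
    special cases: the hierarchical latent variable model (HLVM) fixes the
    between measurement model to the within one
    (``cross_level_equal_loadings`` with marker identification) and drops
    the between residuals; the strict historical variant additionally fixes
    every loading at one and equates the item residuals.
    """

    p_W: int
    p_B: int
    mode: str = "efa"
    pattern_W: np.ndarray = None
    pattern_B: np.ndarray = None
    constraints: frozenset = frozenset()
    rotation: dict = field(default_factory=lambda: {
        "method": "geomin", "epsilon": 0.01, "oblique": True})

    def __post_init__(self):
        if self.mode not in ("efa", "cfa"):
            raise ValueError("mode must be 'efa' or 'cfa'")
        self.constraints = frozenset(self.constraints)
        if self.constraints not in CONSTRAINT_SETS:
            raise ValueError(f"unsupported constraint combination: {set(self.constraints)}")
        if self.mode == "cfa":
            if self.pattern_W is None:
                raise ValueError("CFA requires pattern_W")
            self.pattern_W = np.asarray(self.pattern_W, dtype=bool)
            if self.pattern_W.shape[1] != self.p_W:
                raise ValueError("pattern_W columns must equal p_W")
            if np.any(self.pattern_W.sum(axis=0) < 2):
                raise ValueError("every within factor needs at least 2 loading items")
            if "cross_level_equal_loadings" in self.constraints or \
               "loadings_fixed_one" in self.constraints:
                # between measurement model mirrors the within one
                self.pattern_B = self.pattern_W
                self.p_B = self.p_W
            else:
                if self.pattern_B is None:
                    raise ValueError("CFA requires pattern_B when p_B > 0")
                self.pattern_B = np.asarray(self.pattern_B, dtype=bool)
                if self.pattern_B.shape[1] != self.p_B:
                    raise ValueError("pattern_B columns must equal p_B")
                if np.any(self.pattern_B.sum(axis=0) < 2):
                    raise ValueError("every between factor needs at least 2 loading items")
        elif self.constraints & {"cross_level_equal_loadings", "loadings_fixed_one"}:
            raise ValueError("cross-level constraints require mode='cfa' with a pattern")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def efa(cls, p_W, p_B, **kw):
        return cls(p_W=p_W, p_B=p_B, mode="efa", **kw)

    @classmethod
    def cfa(cls, pattern_W, pattern_B, **kw):
        pattern_W = np.asarray(pattern_W, dtype=bool)
        pattern_B = np.asarray(pattern_B, dtype=bool)
        return cls(p_W=pattern_W.shape[1], p_B=pattern_B.shape[1], mode="cfa",
                   pattern_W=pattern_W, pattern_B=pattern_B, **kw)

    @classmethod
    def hlvm(cls, pattern_W):
        """HLVM: same factors at both levels (marker identification, free
        factor covariances per level), no between item residuals."""
        pattern_W = np.asarray(pattern_W, dtype=bool)
        return cls(p_W=pattern_W.shape[1], p_B=pattern_W.shape[1], mode="cfa",
                   pattern_W=pattern_W,
                   constraints=frozenset({"cross_level_equal_loadings",
                                          "no_between_residuals"}))

    @classmethod
    def sampson_strict(cls, pattern_W):
        """Strict historical variant: loadings fixed at one, equal item
        residual variances, no between item residuals."""
        pattern_W = np.asarray(pattern_W, dtype=bool)
        return cls(p_W=pattern_W.shape[1], p_B=pattern_W.shape[1], mode="cfa",
                   pattern_W=pattern_W,
                   constraints=frozenset({"loadings_fixed_one",
                                          "equal_within_residuals",
                                          "no_between_residuals"}))

    @property
    def is_hlvm(self) -> bool:
        return bool(self.constraints & {"cross_level_equal_loadings", "loadings_fixed_one"})

    def nested_in(self, other: "ModelSpec") -> bool:
        """True when this spec is a constrained version of ``other``."""
        return (self.constraints >= other.constraints
                and self.p_W == other.p_W)


def parameter_ledger(spec: ModelSpec, M: int, K) -> dict:
    """Free-parameter counts per block for a spec on M items."""
    K = np.broadcast_to(np.asarray(K, dtype=int), (M,))
    led = {"thresholds": int(np.sum(K - 1))}
    c = spec.constraints
    if spec.mode == "efa":
        led["loadings_W"] = M * spec.p_W - spec.p_W * (spec.p_W - 1) // 2
        led["psi_W"] = 0
        led["loadings_B"] = M * spec.p_B - spec.p_B * (spec.p_B - 1) // 2
        led["psi_B"] = 0
    elif "loadings_fixed_one" in c:
        led["loadings_W"] = 0
        led["psi_W"] = spec.p_W * (spec.p_W + 1) // 2
        led["loadings_B"] = 0
        led["psi_B"] = spec.p_B * (spec.p_B + 1) // 2
    elif "cross_level_equal_loadings" in c:
        # shared loadings, first item per factor fixed at 1 (marker), factor
        # covariances free at both levels
        led["loadings_W"] = int(spec.pattern_W.sum()) - spec.p_W
        led["psi_W"] = spec.p_W * (spec.p_W + 1) // 2
        led["loadings_B"] = 0
        led["psi_B"] = spec.p_B * (spec.p_B + 1) // 2
    else:
        led["loadings_W"] = int(spec.pattern_W.sum())
        led["psi_W"] = spec.p_W * (spec.p_W - 1) // 2   # unit factor variances
        led["loadings_B"] = int(spec.pattern_B.sum())
        led["psi_B"] = spec.p_B * (spec.p_B - 1) // 2
    led["theta_W"] = 0   # derived under the delta convention
    led["theta_B"] = 0 if "no_between_residuals" in c else M
    return led


def count_df(spec: ModelSpec, M: int, K) -> int:
    """Test degrees of freedom: sample statistics minus free parameters."""
    K = np.broadcast_to(np.asarray(K, dtype=int), (M,))
    stats = int(np.sum(K - 1)) + M * (M - 1) // 2 + M * (M + 1) // 2
    led = parameter_ledger(spec, M, K)
    n_par = sum(led.values())
    df = stats - n_par
    if df < 0:
        raise ValueError(
            f"negative degrees of freedom ({df}): {stats} statistics vs "
            f"parameter ledger {led}")
    return df
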