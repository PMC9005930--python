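"""Candidate model-space enumeration under term-count and correlation limits.

Every combination of covariates of size 1..max_terms is a candidate
variable subset, except that two covariates whose pairwise Pearson
correlation exceeds ``r_cut`` in magnitude may not co-occur in a model.
With 14 covariates and at most six terms this yields 6,475 subsets when
nothing is correlated.  A lifespan filter additionally makes the two
canopy-phenology covariates mutually exclusive by species lifespan:
NDVI maximum (MAXN) for perennials, NDVI amplitude (AMP) for annuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ModelSpec:
    """One algorithm family plus an ordered covariate subset."""

    algorithm_family: str
    variables: tuple[str, ...]
    spec_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.variables) <= 14:
            raise ValueError("1 to 14 variables required")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variables in spec")
        if not self.spec_id:
            object.__setattr__(
                self, "spec_id",
                f"{self.algorithm_family}:{'+'.join(self.variables)}")


def enumerate_models(codes: list[str], corr: pd.DataFrame | np.ndarray,
                     max_terms: int = 6, r_cut: float = 0.7,
                     algorithm_family: str = "any") -> list[ModelSpec]:
    """Enumerate all eligible variable subsets as :class:`ModelSpec`.

    Returns every non-empty subset of ``codes`` of size <= ``max_terms``
    containing no pair with ``|r| > r_cut``, in deterministic
    lexicographic order (by subset size, then code order within
    ``codes``).  Pairs whose correlation is undefined (NaN, e.g. a
    constant layer) are treated as unconstrained.
    """
    if not 0 < r_cut <= 1:
        raise ValueError("r_cut must be in (0, 1]")
    if isinstance(corr, pd.DataFrame):
        corr = corr.loc[codes, codes].to_numpy()
    else:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (len(codes), len(codes)):
            raise ValueError("correlation matrix inconsistent with codes")
    forbidden = set()
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > r_cut:
                forbidden.add((codes[i], codes[j]))

    specs: list[ModelSpec] = []
    for k in range(1, max_terms + 1):
        for combo in combinations(codes, k):
            ok = all((a, b) not in forbidden and (b, a) not in forbidden
                     for a, b in combinations(combo, 2))
            if ok:
                specs.append(ModelSpec(algorithm_family, combo))
    return specs


def lifespan_filter(specs: list[ModelSpec], lifespan: str) -> list[ModelSpec]:
    """Drop specs containing the phenology covariate ineligible for a lifespan.

    Perennial species use NDVI maximum (MAXN), so specs containing AMP
    are dropped; annual species use NDVI amplitude (AMP), so specs
    containing MAXN are dropped.  Specs with neither code pass through.
    """
    if lifespan == "perennial":
        banned = "AMP"
    elif lifespan == "annual":
        banned = "MAXN"
    else:
        raise ValueError(f"unknown lifespan {lifespan!r}")
    return [s for s in specs if banned not in s.variables]


def cap_specs(specs: list[ModelSpec], cap: int | None, seed: int = 0,
              must_include: list[str] | None = None) -> list[ModelSpec]:
    """Optionally subsample the model space to at most ``cap`` specs.

    A seeded uniform subsample keeps desk-scale runs tractable; order of
    the surviving specs is preserved.  Full enumeration is used whenever
    ``cap`` is None or not binding.
    """
    if cap is None or len(specs) <= cap:
        return list(specs)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(specs), size=cap, replace=False))
    return [specs[i] for i in idx]


def specs_to_frame(specs: list[ModelSpec]) -> pd.DataFrame:
    """Spec list as a DataFrame (spec_id, family, variables) for CSV export."""
    return pd.DataFrame({
        "spec_id": [s.spec_id for s in specs],
        "algorithm_family": [s.algorithm_family for s in specs],
        "variables": ["+".join(s.variables) for s in specs],
    })
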