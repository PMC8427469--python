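"""Model specification for the trait-state-occasion (TSO) covariance structure.

The measurement model for ``p = n_substances * n_occasions`` bounded
substance-use scores has three orthogonal layers of latent variables:

* a *common* liability factor loading on every indicator (free loadings),
* one *specific* factor per substance loading on that substance's
  indicators across occasions (free loadings),
* one *occasion* factor per measurement wave loading on the same-wave
  indicators of every substance, with loadings fixed to 1.

All factor variances are fixed to 1 and all factors are mutually
uncorrelated; residual variances and intercepts are free.  Trait factors
(common + specific) may additionally be regressed on observed exogenous
predictors (polygenic scores, sex, principal components), in which case the
factor's *residual* variance stays fixed at 1 and its total variance grows
with the explained part — the MIMIC convention that makes standardised
regression coefficients directly interpretable as correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

DEFAULT_SUBSTANCES = ("cig", "alc", "can", "oth")
DEFAULT_OCCASIONS = ("17", "20", "22")

COMMON = "common"


class SpecError(ValueError):
    """Raised for inconsistent model specifications."""


def _specific(substance: str) -> str:
    return f"spec_{substance}"


def _occasion(occ: str) -> str:
    return f"occ_{occ}"


@dataclass(frozen=True)
class TSOSpec:
    """Structure of a TSO model: factors, loading pattern, structural block.

    ``structural`` maps a trait-factor name (``"common"``, ``"spec_cig"``,
    ...) to the tuple of predictor column names that factor is regressed
    on.  Occasion factors are never regressed.
    """

    substances: tuple[str, ...] = DEFAULT_SUBSTANCES
    occasions: tuple[str, ...] = DEFAULT_OCCASIONS
    structural: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.substances) < 1 or len(self.occasions) < 2:
            raise SpecError("need >= 1 substance and >= 2 occasions")
        known = set(self.trait_factors)
        for factor in self.structural:
            if factor not in known:
                raise SpecError(f"structural map references unknown factor {factor!r}")

    # ------------------------------------------------------------------
    # naming
    # ------------------------------------------------------------------
    @property
    def indicators(self) -> tuple[str, ...]:
        """Substance-major indicator order: cig_17, cig_20, ..., oth_22."""
        return tuple(
            f"{s}_{t}" for s in self.substances for t in self.occasions
        )

    @property
    def n_indicators(self) -> int:
        return len(self.substances) * len(self.occasions)

    @property
    def has_common(self) -> bool:
        # a single substance makes the common factor indistinguishable
        # from its specific factor, so it is dropped
        return len(self.substances) >= 2

    @property
    def has_occasion(self) -> bool:
        # an occasion factor needs >= 2 same-wave indicators to carry
        # shared variance distinct from the residual
        return len(self.substances) >= 2

    @property
    def trait_factors(self) -> tuple[str, ...]:
        base = (COMMON,) if self.has_common else ()
        return base + tuple(_specific(s) for s in self.substances)

    @property
    def occasion_factors(self) -> tuple[str, ...]:
        if not self.has_occasion:
            return ()
        return tuple(_occasion(t) for t in self.occasions)

    @property
    def factors(self) -> tuple[str, ...]:
        return self.trait_factors + self.occasion_factors

    @property
    def predictors(self) -> tuple[str, ...]:
        """Union of structural predictors, first-appearance order."""
        seen: list[str] = []
        for cols in self.structural.values():
            for c in cols:
                if c not in seen:
                    seen.append(c)
        return tuple(seen)

    # ------------------------------------------------------------------
    # loading pattern
    # ------------------------------------------------------------------
    def loading_matrix(
        self, lam_common: np.ndarray | None, lam_specific: np.ndarray
    ) -> np.ndarray:
        """Assemble the p x m loading matrix Lambda from free loadings.

        ``lam_common`` has one entry per indicator (or None when the
        common factor is absent); ``lam_specific`` has one entry per
        indicator, placed in its substance's column.  Occasion columns
        are fixed to 1.
        """
        p = self.n_indicators
        m = len(self.factors)
        lam = np.zeros((p, m))
        col = 0
        if self.has_common:
            lam[:, col] = np.asarray(lam_common, dtype=float)
            col += 1
        n_occ = len(self.occasions)
        for k in range(len(self.substances)):
            rows = slice(k * n_occ, (k + 1) * n_occ)
            lam[rows, col + k] = np.asarray(lam_specific, dtype=float)[rows]
        col += len(self.substances)
        for t in range(len(self.occasion_factors)):
            for k in range(len(self.substances)):
                lam[k * n_occ + t, col + t] = 1.0
        return lam

    # ------------------------------------------------------------------
    # free-parameter bookkeeping
    # ------------------------------------------------------------------
    @property
    def n_free_loadings(self) -> int:
        p = self.n_indicators
        return (p if self.has_common else 0) + p

    @property
    def n_free_cov_params(self) -> int:
        """Free parameters entering the covariance structure only."""
        return self.n_free_loadings + self.n_indicators

    @property
    def n_structural(self) -> int:
        return sum(len(v) for v in self.structural.values())

    @property
    def n_free(self) -> int:
        """Total free parameters: loadings, residuals, intercepts, b."""
        return self.n_free_cov_params + self.n_indicators + self.n_structural

    @property
    def df(self) -> int:
        """Model degrees of freedom over the unique covariance elements."""
        p = self.n_indicators
        return p * (p + 1) // 2 - self.n_free_cov_params

    def param_names(self) -> list[str]:
        names: list[str] = []
        ind = self.indicators
        if self.has_common:
            names += [f"lam_c[{y}]" for y in ind]
        names += [f"lam_s[{y}]" for y in ind]
        names += [f"resid[{y}]" for y in ind]
        names += [f"nu[{y}]" for y in ind]
        for factor in self.trait_factors:
            for x in self.structural.get(factor, ()):
                names.append(f"b[{factor}~{x}]")
        return names

    def structural_index(self) -> list[tuple[int, int]]:
        """(trait-factor index, predictor index) per structural coefficient."""
        preds = self.predictors
        out = []
        for f_idx, factor in enumerate(self.trait_factors):
            for x in self.structural.get(factor, ()):
                out.append((f_idx, preds.index(x)))
        return out


@dataclass
class TSOParameters:
    """Free parameters of a TSOSpec in natural (untransformed) units."""

    lam_common: np.ndarray | None
    lam_specific: np.ndarray
    resid_var: np.ndarray
    intercepts: np.ndarray
    b: np.ndarray  # flat, ordered per TSOSpec.structural_index()

    def pack(self) -> np.ndarray:
        parts = []
        if self.lam_common is not None:
            parts.append(self.lam_common)
        parts += [self.lam_specific, self.resid_var, self.intercepts, self.b]
        return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])


def unpack(spec: TSOSpec, theta: np.ndarray) -> TSOParameters:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free,):
        raise SpecError(
            f"theta has length {theta.size}, spec expects {spec.n_free}"
        )
    p = spec.n_indicators
    pos = 0
    lam_common = None
    if spec.has_common:
        lam_common = theta[pos : pos + p]
        pos += p
    lam_specific = theta[pos : pos + p]
    pos += p
    resid_var = theta[pos : pos + p]
    pos += p
    intercepts = theta[pos : pos + p]
    pos += p
    b = theta[pos:]
    return TSOParameters(lam_common, lam_specific, resid_var, intercepts, b)


def build_spec(
    n_substances: int = 4,
    n_occasions: int = 3,
    structural: Mapping[str, Sequence[str]] | None = None,
    substances: Sequence[str] | None = None,
    occasions: Sequence[str] | None = None,
) -> TSOSpec:
    """Construct a TSOSpec for ``n_substances`` x ``n_occasions`` indicators.

    With the default 4 substances and 3 occasions the baseline model has
    36 free covariance-structure parameters (12 common loadings, 12
    specific loadings, 12 residual variances) against 78 unique
    covariance elements, hence 42 degrees of freedom.
    """
    if substances is None:
        if n_substances <= len(DEFAULT_SUBSTANCES):
            substances = DEFAULT_SUBSTANCES[:n_substances]
        else:
            substances = tuple(f"s{i+1}" for i in range(n_substances))
    if occasions is None:
        if n_occasions <= len(DEFAULT_OCCASIONS):
            occasions = DEFAULT_OCCASIONS[:n_occasions]
        else:
            occasions = tuple(f"t{i+1}" for i in range(n_occasions))
    struct = {}
    if structural:
        struct = {f: tuple(v) for f, v in structural.items()}
    return TSOSpec(tuple(substances), tuple(occasions), struct)
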