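"""Nested-model comparison of mechanism fits by F-test on RSS improvement."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

from scipy.stats import f as f_dist

from .fit import FitResult, ParameterSet, fit_global, promote_to_model2
from .ramp import Trace

__all__ = ["FTestResult", "f_test", "compare_mechanisms"]

_NESTED = {("model1", "model2")}


@dataclass(frozen=True)
class FTestResult:
    F: float
    p: float
    df1: int
    df2: int
    rss_simple: float
    rss_complex: float
    threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.F < 0 or not (0.0 <= self.p <= 1.0):
            raise ValueError("invalid F statistic or p-value")
        if self.df1 < 1 or self.df2 < 1:
            raise ValueError("degrees of freedom must be >= 1")

    @property
    def significant(self) -> bool:
        return self.p <= self.threshold

    def to_dict(self) -> Dict[str, object]:
        return {
            "F": self.F,
            "p": self.p,
            "df1": self.df1,
            "df2": self.df2,
            "rss_simple_AU2": self.rss_simple,
            "rss_complex_AU2": self.rss_complex,
            "threshold": self.threshold,
            "decision": "complex" if self.significant else "simple",
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def f_test(
    fit_simple: FitResult, fit_complex: FitResult, threshold: float = 0.01
) -> FTestResult:
    """F-test for the RSS improvement of a nested, more complex mechanism.

    ``F = ((RSS1 - RSS2)/df1) / (RSS2/df2)`` with ``df1 = p2 - p1`` and
    ``df2 = n - p2``; ``p`` is the upper tail of F(df1, df2).  If the
    complex fit is (numerically) worse, F is clamped to 0 with a warning.
    """
    pair = (fit_simple.params.model_name, fit_complex.params.model_name)
    if pair not in _NESTED:
        raise ValueError(f"models {pair} are not nested (simple, complex)")
    if fit_simple.n_points != fit_complex.n_points:
        raise ValueError("fits compare different datasets (n_points differ)")
    df1 = fit_complex.n_params - fit_simple.n_params
    df2 = fit_complex.n_points - fit_complex.n_params
    if df1 < 1 or df2 < 1:
        raise ValueError("nonpositive degrees of freedom")
    rss1, rss2 = fit_simple.rss, fit_complex.rss
    if rss2 > rss1:
        warnings.warn(
            "complex fit has higher RSS than simple fit (optimizer noise); "
            "clamping F to 0",
            stacklevel=2,
        )
        F = 0.0
    elif rss2 == 0.0:
        F = float("inf") if rss1 > 0 else 0.0
    else:
        F = ((rss1 - rss2) / df1) / (rss2 / df2)
    p = 1.0 if F == 0.0 else float(f_dist.sf(F, df1, df2))
    return FTestResult(F=float(F), p=p, df1=df1, df2=df2,
                       rss_simple=rss1, rss_complex=rss2, threshold=threshold)


def compare_mechanisms(
    dataset: Sequence[Trace],
    init_simple: ParameterSet,
    init_complex: Optional[ParameterSet] = None,
    *,
    threshold: float = 0.01,
    n_starts: int = 1,
    seed: int = 0,
    **fit_kwargs,
) -> Tuple[FitResult, FitResult, FTestResult]:
    """Fit model1 and model2 to the same dataset and F-test the improvement.

    The complex fit is always warm-started from the simple optimum (with a
    near-inert trap step), so its RSS cannot exceed the simple fit's by
    more than optimizer noise; ``init_complex`` adds a second, informative
    start for the trap parameters.
    """
    fit_simple = fit_global(dataset, init_simple, n_starts=n_starts, seed=seed,
                            **fit_kwargs)
    inits = [promote_to_model2(fit_simple.params)]
    if init_complex is not None:
        inits.append(init_complex)
    fit_complex = fit_global(dataset, inits, n_starts=max(n_starts, len(inits)),
                             seed=seed, **fit_kwargs)
    return fit_simple, fit_complex, f_test(fit_simple, fit_complex, threshold)
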