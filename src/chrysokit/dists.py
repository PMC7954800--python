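"""Named length-distribution families used by the synthetic-genome generator.

A distribution spec is either a number (constant) or a string in one of the
forms ``constant(v)``, ``uniform(a,b)`` (integer endpoints, inclusive) or
``lognormal(mu,sigma)`` (parameters of the underlying normal; samples are
rounded to integers and floored at 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

_SPEC_RE = re.compile(r"^\s*(constant|uniform|lognormal)\s*\(([^)]*)\)\s*$")


@dataclass(frozen=True)
class DistSpec:
    """A parsed length distribution: one of constant/uniform/lognormal."""

    family: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | int:
        if self.family == "constant":
            val = int(round(self.params[0]))
            return val if size is None else np.full(size, val, dtype=np.int64)
        if self.family == "uniform":
            a, b = (int(self.params[0]), int(self.params[1]))
            out = rng.integers(a, b + 1, size=1 if size is None else size)
        else:  # lognormal
            mu, sigma = self.params
            out = np.maximum(1, np.rint(rng.lognormal(mu, sigma, size=1 if size is None else size))).astype(np.int64)
        return int(out[0]) if size is None else np.asarray(out, dtype=np.int64)

    @property
    def mean(self) -> float:
        if self.family == "constant":
            return float(self.params[0])
        if self.family == "uniform":
            return (self.params[0] + self.params[1]) / 2.0
        mu, sigma = self.params
        return float(np.exp(mu + sigma**2 / 2.0))


def parse_dist(spec) -> DistSpec:
    """Parse a distribution spec (number, DistSpec, or ``family(a,b)`` string)."""
    if isinstance(spec, DistSpec):
        return spec
    if isinstance(spec, (int, float)):
        if spec <= 0:
            raise ValueError(f"constant length must be positive, got {spec}")
        return DistSpec("constant", (float(spec),))
    m = _SPEC_RE.match(str(spec))
    if not m:
        raise ValueError(f"unrecognised distribution spec: {spec!r}")
    family, args = m.group(1), m.group(2)
    params = tuple(float(x) for x in args.split(",")) if args.strip() else ()
    n_expected = {"constant": 1, "uniform": 2, "lognormal": 2}[family]
    if len(params) != n_expected:
        raise ValueError(f"{family} takes {n_expected} parameter(s), got {len(params)}")
    if family == "uniform" and params[1] < params[0]:
        raise ValueError("uniform(a,b) requires a <= b")
    if family in ("constant", "uniform") and params[0] <= 0:
        raise ValueError("lengths must be positive")
    return DistSpec(family, params)
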