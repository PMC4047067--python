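"""Founder-age estimation with the rho statistic under a linear clock.

rho is the mean number of mutations separating a set of sequences from a
designated founder haplotype.  Under a star genealogy (all lineages
radiating independently from the founder) the mutation counts are
independent Poisson draws, rho is their sample mean, and its standard
error is sqrt(rho / n).  Multiplying by a clock (years per mutation on the
whole molecule; default one mutation per 3533 years for the complete mtDNA
genome) converts rho to an age in years before present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import sqrt

import numpy as np

from .seqdata import Alignment
from .errors import AlignmentError

#: default whole-genome clock, years per mutation
DEFAULT_CLOCK_YEARS = 3533.0

#: per-site per-year substitution rate behind the whole-genome clock
SITE_RATE_PER_YEAR = 1.665e-8


def clock_from_site_rate(alignment_length: int, site_rate: float = SITE_RATE_PER_YEAR) -> float:
    """Years per mutation implied by a per-site rate and an alignment length."""
    return 1.0 / (site_rate * alignment_length)


@dataclass
class RhoResult:
    rho: float
    sigma: float
    n: int
    clock_years_per_mutation: float
    age_bp: float
    age_range_bp: tuple[float, float]

    def to_json_dict(self) -> dict:
        return {
            "rho": self.rho,
            "sigma": self.sigma,
            "n": self.n,
            "clock_years_per_mutation": self.clock_years_per_mutation,
            "age_bp": self.age_bp,
            "age_range_bp": list(self.age_range_bp),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def rho_estimate(
    aln: Alignment,
    founder: str,
    clock: float = DEFAULT_CLOCK_YEARS,
) -> RhoResult:
    """rho dating of a sequence cluster against a founder haplotype.

    Differences are counted with pairwise deletion of missing bases.  The
    age range is ``(rho +/- 1.96 * sigma) * clock``, clipped at zero.
    """
    founder = founder.upper()
    if len(founder) != aln.n_columns:
        raise AlignmentError(
            f"founder length {len(founder)} does not match alignment width "
            f"{aln.n_columns}"
        )
    f = np.array(list(founder), dtype="<U1")
    valid_f = np.isin(f, list("ACGT"))
    valid_s = np.isin(aln.bases, list("ACGT"))
    diffs = ((aln.bases != f[None, :]) & valid_s & valid_f[None, :]).sum(axis=1)
    n = aln.n_samples
    rho = float(diffs.mean())
    sigma = sqrt(rho / n)
    lo = max(rho - 1.96 * sigma, 0.0) * clock
    hi = (rho + 1.96 * sigma) * clock
    return RhoResult(
        rho=rho,
        sigma=sigma,
        n=n,
        clock_years_per_mutation=clock,
        age_bp=rho * clock,
        age_range_bp=(lo, hi),
    )
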