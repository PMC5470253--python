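"""Bayesian PSI estimation and clone-vs-parent splice-event calling.

The inclusion/exclusion junction counts (x out of m) are modelled as
binomial with a conjugate Beta prior, so the PSI posterior is
Beta(x + a, m - x + b) and everything — posterior mean, credible
interval, and the two-model Bayes factor — is available in closed form.

The Bayes factor compares
  H1: independent PSI in the two samples, each with a uniform prior,
  H0: a single shared PSI with a uniform prior,
giving BF = B(x_a+1, m_a-x_a+1) B(x_b+1, m_b-x_b+1)
            / B(x_a+x_b+1, m_a+m_b-x_a-x_b+1),
symmetric in the two samples.  Events are called with the conjunction of
three configurable thresholds: |dPSI| >= 0.2, total junction reads >= 10
in each sample, and BF >= 10 (the conventional stringent cutoffs for
junction-based event calling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

__all__ = [
    "PsiEstimate",
    "SpliceEvent",
    "Thresholds",
    "InvalidCountsError",
    "SampleMismatchError",
    "NoReplicatesError",
    "estimate_psi_posterior",
    "bayes_factor",
    "call_events",
    "replicate_summary",
    "shared_events",
    "events_to_frame",
]


class InvalidCountsError(ValueError):
    """x > m or negative counts."""


class SampleMismatchError(ValueError):
    """Clone and parent carry different cassette sets."""


class NoReplicatesError(ValueError):
    """Empty replicate list."""


@dataclass(frozen=True)
class PsiEstimate:
    """Point estimate and Beta posterior summary of PSI."""

    psi: float
    x_inclusion: int
    m_total: int
    posterior_mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class Thresholds:
    delta_min: float = 0.2
    reads_min: int = 10
    bf_min: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.delta_min <= 1.0):
            raise ValueError("delta_min must lie in [0, 1]")
        if self.reads_min < 0:
            raise ValueError("reads_min must be non-negative")
        if self.bf_min < 0:
            raise ValueError("bf_min must be non-negative")


@dataclass(frozen=True)
class SpliceEvent:
    gene: str
    cassette: tuple[int, int, int]
    psi_parent: PsiEstimate
    psi_clone: PsiEstimate
    delta_psi: float
    total_reads_parent: int
    total_reads_clone: int
    bayes_factor: float
    passes: bool


def estimate_psi_posterior(
    x_inclusion: int, m_total: int, prior: tuple[float, float] = (1.0, 1.0)
) -> PsiEstimate:
    """Conjugate Beta posterior of PSI from x inclusion-supporting reads
    out of m informative reads; credible interval is the central 95%."""
    x, m = x_inclusion, m_total
    if x < 0 or m < 0 or x > m:
        raise InvalidCountsError("invalid counts")
    a, b = prior
    post = stats.beta(x + a, m - x + b)
    mean = (x + a) / (m + a + b)
    ci_low, ci_high = post.ppf(0.025), post.ppf(0.975)
    psi = x / m if m > 0 else math.nan
    return PsiEstimate(
        psi=psi,
        x_inclusion=x,
        m_total=m,
        posterior_mean=float(mean),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def bayes_factor(x_a: int, m_a: int, x_b: int, m_b: int) -> float:
    """Closed-form Bayes factor for differing vs shared PSI.

    Marginal likelihood ratio of the independent-PSI model over the
    shared-PSI model, both under uniform Beta(1,1) priors; the binomial
    coefficients cancel.  Values above 1 favor a PSI difference.
    """
    for x, m in ((x_a, m_a), (x_b, m_b)):
        if x < 0 or m < 0 or x > m:
            raise InvalidCountsError("invalid counts")
    log_bf = (
        betaln(x_a + 1, m_a - x_a + 1)
        + betaln(x_b + 1, m_b - x_b + 1)
        - betaln(x_a + x_b + 1, m_a + m_b - x_a - x_b + 1)
    )
    return float(np.exp(log_bf))


def call_events(
    clone: dict[tuple[int, int, int], tuple[int, int]],
    parent: dict[tuple[int, int, int], tuple[int, int]],
    gene: str = "gene",
    thresholds: Thresholds = Thresholds(),
    prior: tuple[float, float] = (1.0, 1.0),
) -> list[SpliceEvent]:
    """Call clone-vs-parent splice events per cassette exon.

    ``clone`` and ``parent`` map each cassette (up, mid, down) to its
    (x_inclusion, m_total) junction counts; both must cover the same
    cassettes.  dPSI is the difference of posterior means (clone minus
    parent), which stays defined at low counts.  The read filter is
    applied per sample: both m's must reach ``reads_min``.
    """
    if set(clone) != set(parent):
        raise SampleMismatchError("sample mismatch")
    events = []
    for cassette in sorted(clone):
        xc, mc = clone[cassette]
        xp, mp = parent[cassette]
        est_c = estimate_psi_posterior(xc, mc, prior)
        est_p = estimate_psi_posterior(xp, mp, prior)
        delta = est_c.posterior_mean - est_p.posterior_mean
        bf = bayes_factor(xp, mp, xc, mc)
        passes = (
            abs(delta) >= thresholds.delta_min
            and min(mc, mp) >= thresholds.reads_min
            and bf >= thresholds.bf_min
        )
        events.append(
            SpliceEvent(
                gene=gene,
                cassette=cassette,
                psi_parent=est_p,
                psi_clone=est_c,
                delta_psi=float(delta),
                total_reads_parent=mp,
                total_reads_clone=mc,
                bayes_factor=bf,
                passes=passes,
            )
        )
    return events


def replicate_summary(psi_values: Iterable[float]) -> tuple[float, float]:
    """Mean and sample s.d. of replicate PSI values on the percent scale.

    Single replicate: the s.d. is NaN (undefined), matching the
    mean ± s.d. convention of exon-inclusion tables.
    """
    vals = np.asarray(list(psi_values), dtype=float)
    if vals.size == 0:
        raise NoReplicatesError("no replicates")
    mean = 100.0 * vals.mean()
    sd = 100.0 * vals.std(ddof=1) if vals.size > 1 else math.nan
    return float(mean), float(sd)


def shared_events(
    events_a: Iterable[SpliceEvent], events_b: Iterable[SpliceEvent]
) -> list[tuple[str, tuple[int, int, int], str]]:
    """Passing events shared by two clones with the same dPSI direction.

    Returns (gene, cassette, direction) tuples, direction being
    'inclusion' (dPSI > 0) or 'exclusion'.
    """

    def keyed(events):
        out = {}
        for ev in events:
            if ev.passes and ev.delta_psi != 0:
                out[(ev.gene, ev.cassette)] = (
                    "inclusion" if ev.delta_psi > 0 else "exclusion"
                )
        return out

    ka, kb = keyed(events_a), keyed(events_b)
    shared = []
    for key in sorted(set(ka) & set(kb), key=str):
        if ka[key] == kb[key]:
            shared.append((key[0], key[1], ka[key]))
    return shared


def events_to_frame(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    """Tabular event list for TSV output."""
    rows = []
    for ev in events:
        rows.append(
            {
                "gene": ev.gene,
                "cassette": "-".join(str(l) for l in ev.cassette),
                "psi_parent": ev.psi_parent.posterior_mean,
                "psi_clone": ev.psi_clone.posterior_mean,
                "delta_psi": ev.delta_psi,
                "reads_parent": ev.total_reads_parent,
                "reads_clone": ev.total_reads_clone,
                "bayes_factor": ev.bayes_factor,
                "passes": ev.passes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cassette",
            "psi_parent",
            "psi_clone",
            "delta_psi",
            "reads_parent",
            "reads_clone",
            "bayes_factor",
            "passes",
        ],
    )
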