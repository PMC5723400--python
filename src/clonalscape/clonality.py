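"""Clone identification, marker power, and clonal richness.

Samples sharing a full multilocus genotype (MLG) are treated as ramets of
one genet (one clone). Clonal richness is R = (G - 1)/(N - 1) for G
distinct MLGs among N ramets: 0 means monoclonal, 1 means every sample a
distinct genet. Marker power is quantified by the probability of identity
P_ID — the probability that two individuals drawn at random share an MLG
under Hardy-Weinberg equilibrium — accumulated over locus combinations,
and by the expected number of duplicate-genotype pairs C(N,2) * P_ID.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype_io import AlleleFrequencyTable, GenotypeMatrix


class UndefinedRichnessError(ValueError):
    """Richness requires at least two samples."""


@dataclass
class MLGAssignment:
    """Partition of one site's samples into multilocus genotypes."""

    site_id: str
    labels: dict  # sample_id -> MLG integer label (0-based, dense)
    G: int
    N: int
    policy: str


@dataclass
class RichnessRecord:
    site_id: str
    species: str
    N: int
    G: int
    R: float


@dataclass
class PIDProfile:
    """Per-locus and cumulative probability of identity.

    ``cumulative[k-1]`` is the P_ID after the first k loci of
    ``locus_order``; ``expected_duplicates`` is C(N,2) times the full
    cumulative value.
    """

    locus_order: list
    per_locus: list
    cumulative: list
    n: int
    expected_duplicates: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": self.locus_order,
            "pid_locus": self.per_locus,
            "pid_cumulative": self.cumulative,
        })


def identify_mlgs(g: GenotypeMatrix, policy: str = "strict") -> MLGAssignment:
    """Assign samples to multilocus genotypes.

    strict
        Two samples share an MLG iff all L normalized calls are equal;
        a missing call equals only another missing call. This induces a
        partition (equivalence classes of the genotype vector).
    missing_wildcard
        Samples are linked when every locus at which both are non-missing
        matches; MLGs are the connected components of the link graph, so
        a sample with missing data can bridge otherwise distinct samples.
    """
    n = g.n_samples
    if n < 1:
        raise UndefinedRichnessError("need at least one sample")
    if policy == "strict":
        seen: dict = {}
        labels = {}
        for sid, row in zip(g.sample_ids, g.calls):
            key = tuple(row)
            if key not in seen:
                seen[key] = len(seen)
            labels[sid] = seen[key]
        return MLGAssignment(site_id=g.site_id, labels=labels,
                             G=len(seen), N=n, policy=policy)
    if policy == "missing_wildcard":
        rows_i, cols_j = [], []
        for i in range(n):
            for j in range(i + 1, n):
                linked = True
                for a, b in zip(g.calls[i], g.calls[j]):
                    if a is not None and b is not None and a != b:
                        linked = False
                        break
                if linked:
                    rows_i.append(i)
                    cols_j.append(j)
        adj = csr_matrix(
            (np.ones(len(rows_i)), (rows_i, cols_j)), shape=(n, n)
        )
        n_comp, comp = connected_components(adj, directed=False)
        # densify component ids in sample order
        remap: dict = {}
        labels = {}
        for sid, c in zip(g.sample_ids, comp):
            if c not in remap:
                remap[c] = len(remap)
            labels[sid] = remap[c]
        return MLGAssignment(site_id=g.site_id, labels=labels,
                             G=n_comp, N=n, policy=policy)
    raise ValueError(f"unknown MLG policy {policy!r}")


def clonal_richness(a: MLGAssignment, species: str = "") -> RichnessRecord:
    """R = (G - 1)/(N - 1); undefined for N < 2."""
    if a.N < 2:
        raise UndefinedRichnessError(
            f"richness undefined for N={a.N} at site {a.site_id!r}"
        )
    return RichnessRecord(site_id=a.site_id, species=species,
                          N=a.N, G=a.G, R=(a.G - 1) / (a.N - 1))


def pid_single_locus(p: "dict | list") -> float:
    """P_ID for one locus: sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2.

    Equals the probability that two random HWE genotypes at the locus are
    identical, i.e. the sum over unordered genotypes of their squared HWE
    probabilities.
    """
    vals = list(p.values()) if isinstance(p, dict) else list(p)
    s = sum(v ** 4 for v in vals)
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            s += (2 * vals[i] * vals[j]) ** 2
    return s


def probability_of_identity(
    f: AlleleFrequencyTable,
    n: int,
    locus_order: str = "most_informative_first",
) -> PIDProfile:
    """P_ID over increasing locus combinations, plus expected duplicates.

    ``most_informative_first`` sorts loci by ascending per-locus P_ID
    (most discriminating first, ties broken by locus id), the conventional
    ordering for a marker-power curve; ``given`` keeps the table's order.
    The cumulative P_ID after k loci is the product of the first k
    per-locus values (loci assumed independent).
    """
    if not f.locus_ids:
        raise ValueError("empty allele frequency table")
    per = {locus: pid_single_locus(f.freqs[locus]) for locus in f.locus_ids}
    if locus_order == "most_informative_first":
        order = sorted(f.locus_ids, key=lambda l: (per[l], l))
    elif locus_order == "given":
        order = list(f.locus_ids)
    else:
        raise ValueError(f"unknown locus order {locus_order!r}")
    per_sorted = [per[l] for l in order]
    cumulative = list(np.cumprod(per_sorted))
    e = expected_duplicates(cumulative[-1], n)
    return PIDProfile(locus_order=order, per_locus=per_sorted,
                      cumulative=cumulative, n=n, expected_duplicates=e)


def expected_duplicates(pid: float, n: int, form: str = "pairwise") -> float:
    """Expected duplicate count from a cumulative P_ID and sample size.

    ``pairwise`` (default) is C(n,2) * pid, the expected number of sample
    pairs sharing an MLG by chance — the direct consequence of P_ID being
    a two-individual probability. ``per_individual`` returns n * pid as an
    alternative reading of "expected number of individuals with the same
    genotype".
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    if not (0 < pid <= 1):
        raise ValueError(f"pid must be in (0, 1], got {pid}")
    if form == "pairwise":
        return math.comb(n, 2) * pid
    if form == "per_individual":
        return n * pid
    raise ValueError(f"unknown form {form!r}")


def richness_table(records: "list[RichnessRecord]") -> pd.DataFrame:
    """Stack per-site richness records into the site x species table."""
    return pd.DataFrame(
        [{"site_id": r.site_id, "species": r.species,
          "N": r.N, "G": r.G, "R": r.R} for r in records]
    )
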