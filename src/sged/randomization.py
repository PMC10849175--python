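"""Monte-Carlo randomization of site groups and empirical p-values.

Null distributions for group statistics are obtained by re-sampling random
groups of the same size from a pool of candidate sites.  Within one
replicate group a site is drawn at most once; across replicates (and
across test groups) sites may recur.  Sampling can be *conditional*: each
replicate member is drawn among candidates whose covariate (e.g. RSA) lies
within a similarity threshold of the matched test site's value, which
controls for that covariate in the test.  For skewed covariates the window
mean can differ from the test value; an optional bias correction recenters
each sampling window until its candidate mean matches the test value
(implemented here as iterative window recentering — see the methods note).

The empirical upper-tail p-value is ``(#{sim ≥ obs} + 1) / (N + 1)``: the
add-one ("pseudo-count") form counts the observed group as one more
replicate, so p can never be zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Group, SgedError, SgedRecord, SgedTable

__all__ = [
    "RandomizationSpec",
    "RandomizationResult",
    "PValueResult",
    "randomize_groups",
    "conditional_sample",
    "empirical_pvalue",
]

DEFAULT_SEED = 20240122


@dataclass
class RandomizationSpec:
    """Parameters of a randomization run.

    ``condition_column`` names the covariate column in the sites table;
    ``similarity_threshold`` (same units as the covariate, required exactly
    when a condition column is set; 0 means exact matching) bounds the
    per-site covariate difference.  ``seed`` feeds a numpy
    ``default_rng`` so runs are fully reproducible.
    """

    n_replicates: int
    condition_column: str | None = None
    similarity_threshold: float | None = None
    bias_correction: bool = False
    seed: int = DEFAULT_SEED
    exclude_test_sites: bool = False

    def __post_init__(self):
        if self.n_replicates < 1:
            raise SgedError("n_replicates must be positive")
        if (self.condition_column is None) != (self.similarity_threshold is None):
            raise SgedError(
                "similarity_threshold is required exactly when condition_column is set"
            )
        if self.similarity_threshold is not None and self.similarity_threshold < 0:
            raise SgedError("similarity_threshold must be nonnegative")


@dataclass
class RandomizationResult:
    """Replicate groups as an SGED table plus structured access.

    ``replicates`` has columns ``Group``, ``Replicate``, ``Source`` (the
    originating test group); ``groups_by_test[i][r]`` is the sampled
    :class:`Group` for test group ``i``, replicate ``r``.
    """

    replicates: SgedTable
    groups_by_test: list
    spec: RandomizationSpec


@dataclass
class PValueResult:
    pvalue: float
    n_extreme: int  # |S_sim ≥ S_obs| (or ≤ for the lower tail)
    n_replicates: int
    tail: str


def empirical_pvalue(observed: float, simulated, tail: str = "upper") -> PValueResult:
    """Empirical Monte-Carlo p-value with the add-one correction.

    Upper tail: ``(#{sim ≥ obs} + 1) / (N + 1)``; the lower tail mirrors
    with ≤.  Ties count as extreme.
    """
    simulated = np.asarray(list(simulated), dtype=float)
    if simulated.size == 0:
        raise SgedError("need at least one simulated statistic")
    if tail == "upper":
        n_extreme = int(np.sum(simulated >= observed))
    elif tail == "lower":
        n_extreme = int(np.sum(simulated <= observed))
    else:
        raise SgedError(f"unknown tail {tail!r}")
    n = int(simulated.size)
    return PValueResult((n_extreme + 1) / (n + 1), n_extreme, n, tail)


def conditional_sample(
    test_values,
    candidates,
    threshold: float,
    bias_correction: bool,
    rng,
    max_recenter: int = 10,
) -> Group:
    """Draw one conditional replicate group.

    ``candidates`` is a list of ``(coordinate, covariate value)``.  For each
    test value ``v`` (in order) one candidate with ``|value − v| ≤
    threshold`` is drawn uniformly and removed from the pool.  With
    ``bias_correction``, the eligibility window is first recentered: the
    window is shifted by the signed discrepancy between its candidate mean
    and ``v``, iterated at most ``max_recenter`` times or until the
    discrepancy falls below ``threshold / 100``, making the expected drawn
    value match ``v`` even for skewed pools.
    """
    values = np.array([v for _, v in candidates], dtype=float)
    remaining = list(range(len(candidates)))
    picked: list = []
    for v in test_values:
        rem = np.array(remaining)
        eligible = rem[np.abs(values[rem] - v) <= threshold]
        if eligible.size == 0:
            raise SgedError(
                f"no candidate site within {threshold} of covariate value {v}"
            )
        if bias_correction:
            center = float(v)
            for _ in range(max_recenter):
                window = rem[np.abs(values[rem] - center) <= threshold]
                if window.size == 0:
                    break  # keep the last non-empty window
                eligible = window
                discrepancy = float(values[eligible].mean()) - float(v)
                if abs(discrepancy) < threshold / 100.0:
                    break
                center -= discrepancy
        choice = int(rng.choice(eligible))
        picked.append(candidates[choice][0])
        remaining.remove(choice)
    return Group(tuple(picked))


def _pool_from_sites(sites: SgedTable, condition_column: str | None):
    """Candidate (coordinate, covariate) pairs from a sites table."""
    pool: list = []
    seen: set = set()
    for i, rec in enumerate(sites.records):
        value = None
        if condition_column is not None:
            if condition_column not in sites.header:
                raise SgedError(f"condition column {condition_column!r} not in sites table")
            raw = rec.attributes[condition_column]
            if raw == "NA":
                warnings.warn(
                    f"sites record {i}: covariate {condition_column!r} is NA, excluded",
                    stacklevel=3,
                )
                continue
            value = float(raw)
        for coord in rec.group:
            if coord is None:
                continue
            if coord in seen:
                warnings.warn(f"duplicate candidate site {coord} ignored", stacklevel=3)
                continue
            seen.add(coord)
            pool.append((coord, value))
    if not pool:
        raise SgedError("candidate site pool is empty")
    return pool


def randomize_groups(
    test: SgedTable, sites: SgedTable, spec: RandomizationSpec
) -> RandomizationResult:
    """Generate random replicate groups matching each test group's size.

    For every record of ``test`` and every replicate, a subset of the
    candidate sites of the same size is drawn without replacement within
    the group (unconditionally uniform, or conditioned per site on the
    covariate named in the spec).  Replicates are independent across test
    groups and fully reproducible from ``spec.seed``.  With
    ``exclude_test_sites``, a test group's own sites are removed from its
    sampling pool.
    """
    pool = _pool_from_sites(sites, spec.condition_column)
    cov_by_coord = {c: v for c, v in pool}
    rng = np.random.default_rng(spec.seed)

    out_records: list = []
    groups_by_test: list = []
    for trec in test.records:
        members = [c for c in trec.group if c is not None]
        if not members:
            raise SgedError("test group has no usable coordinates")
        this_pool = pool
        if spec.exclude_test_sites:
            exclude = set(members)
            this_pool = [(c, v) for c, v in pool if c not in exclude]
        k = len(members)
        if k > len(this_pool):
            raise SgedError(
                f"test group of size {k} exceeds candidate pool of size {len(this_pool)}"
            )
        test_values = None
        if spec.condition_column is not None:
            test_values = []
            for c in members:
                if c not in cov_by_coord:
                    raise SgedError(
                        f"test site {c} has no covariate value in the sites table"
                    )
                test_values.append(cov_by_coord[c])
        source = str(trec.group)
        replicate_groups: list = []
        for r in range(1, spec.n_replicates + 1):
            if spec.condition_column is None:
                idx = rng.choice(len(this_pool), size=k, replace=False)
                group = Group(tuple(this_pool[int(i)][0] for i in idx))
            else:
                group = conditional_sample(
                    test_values,
                    this_pool,
                    spec.similarity_threshold,
                    spec.bias_correction,
                    rng,
                )
            replicate_groups.append(group)
            out_records.append(
                SgedRecord(group, {"Replicate": str(r), "Source": source})
            )
        groups_by_test.append(replicate_groups)

    comments = [
        f"# randomization seed: {spec.seed}",
        f"# replicates per test group: {spec.n_replicates}",
    ]
    if spec.condition_column is not None:
        comments.append(
            f"# conditioned on: {spec.condition_column} "
            f"(threshold {spec.similarity_threshold}, "
            f"bias correction {'on' if spec.bias_correction else 'off'})"
        )
    table = SgedTable(["Group", "Replicate", "Source"], out_records, comments)
    return RandomizationResult(table, groups_by_test, spec)
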