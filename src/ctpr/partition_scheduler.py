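"""Deterministic blocked-update scheduler for coordinate descent.

For biobank-scale data, coefficients can be partitioned into q disjoint
SNP subgroups, grouped into s ordered core-groups. Within a core-group
every subgroup updates its coefficients simultaneously (each from the
state frozen at the start of the core-group step); core-groups execute
strictly in order, so later groups see the earlier groups' fresh
coefficients while earlier groups saw the later groups' stale ones.

Two exact limits: with s = q every core-group holds a single subgroup
and the schedule reduces to ordinary sequential coordinate descent in
partition order; with q = 1 there is a single subgroup and the schedule
is sequential in file order. Both are bitwise-identical to
:func:`ctpr.solver.fit` on the matching visiting order, because the
per-coordinate arithmetic is shared.

This module simulates the parallel schedule deterministically in a
single process: the contract is the update order and communication
semantics, not the transport.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from ctpr.io_formats import GenotypeMatrix
from ctpr.penalty_core import PenaltySpec
from ctpr.solver import (
    _REL_FLOOR,
    CoefficientState,
    FitData,
    _converge,
    _update_one,
    zero_state,
)

__all__ = ["PartitionPlan", "make_partition", "blocked_fit"]


@dataclass
class PartitionPlan:
    """q disjoint SNP index subgroups and s ordered core-groups of them."""

    subgroups: list[np.ndarray]  # I^1..I^q: SNP indices
    core_groups: list[np.ndarray]  # A^1..A^s: subgroup indices, in order

    def __post_init__(self) -> None:
        self.subgroups = [np.asarray(g, dtype=np.intp) for g in self.subgroups]
        self.core_groups = [np.asarray(g, dtype=np.intp) for g in self.core_groups]
        all_snps = np.concatenate([g for g in self.subgroups]) if self.subgroups else np.array([])
        if len(np.unique(all_snps)) != all_snps.size:
            raise ValueError("subgroups overlap")
        cg = np.concatenate(self.core_groups) if self.core_groups else np.array([])
        if sorted(cg.tolist()) != list(range(len(self.subgroups))):
            raise ValueError("core-groups must cover each subgroup exactly once")

    @property
    def q(self) -> int:
        return len(self.subgroups)

    @property
    def s(self) -> int:
        return len(self.core_groups)

    @property
    def n_snps(self) -> int:
        return sum(g.size for g in self.subgroups)

    def flat_order(self) -> np.ndarray:
        """SNP visiting order induced by the schedule (core-groups, then
        subgroups, then within-subgroup order)."""
        return np.concatenate(
            [self.subgroups[h] for cg in self.core_groups for h in cg]
        )

    def to_json(self, path) -> None:
        obj = {
            "subgroups": [g.tolist() for g in self.subgroups],
            "core_groups": [g.tolist() for g in self.core_groups],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "PartitionPlan":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(subgroups=obj["subgroups"], core_groups=obj["core_groups"])


def make_partition(snp_metadata, q: int, s: int, strategy: str = "round_robin") -> PartitionPlan:
    """Build a partition plan over P SNPs.

    ``snp_metadata`` is a SNP count or a GenotypeMatrix (genomic/file
    order is used as is). Strategies:

    * ``round_robin`` (default): SNP j goes to subgroup j mod q, which
      maximizes within-subgroup genomic spacing — a proxy for low LD
      when SNPs are in genomic order.
    * ``chunk``: contiguous blocks of SNPs per subgroup.

    Core-groups are s contiguous, near-equal blocks of subgroup indices.
    The s = q exactness guarantee holds for any partition.
    """
    P = snp_metadata.n_snps if isinstance(snp_metadata, GenotypeMatrix) else int(snp_metadata)
    if not 1 <= q <= P:
        raise ValueError(f"need 1 <= q <= P, got q={q}, P={P}")
    if not 1 <= s <= q:
        raise ValueError(f"need 1 <= s <= q, got s={s}, q={q}")
    idx = np.arange(P)
    if strategy == "round_robin":
        subgroups = [idx[h::q] for h in range(q)]
    elif strategy == "chunk":
        subgroups = list(np.array_split(idx, q))
    else:
        raise ValueError(f"unknown partition strategy {strategy!r}")
    core_groups = list(np.array_split(np.arange(q), s))
    return PartitionPlan(subgroups=subgroups, core_groups=core_groups)


def _blocked_sweep(data, spec, beta, residuals, plan, active_mask=None) -> float:
    """One blocked cycle honoring the freeze/communication semantics.

    Traits outer (cross-trait terms always read the other traits'
    current coefficients, as in the sequential sweep); within a trait,
    core-groups run in order. A multi-subgroup core-group snapshots the
    residual once; each subgroup works on its own copy (so siblings see
    only frozen values) and the coordinate deltas are merged back into
    the global residual per coordinate afterwards. A singleton
    core-group updates the global residual in place, which is the same
    arithmetic sequence, kept explicit so the s = q limit is bitwise
    equal to sequential descent.
    """
    max_rel = 0.0
    for k in range(data.K):
        XT = data.XTs[k]
        r = residuals[k]
        valid = data.valid[k]
        for cg in plan.core_groups:
            if cg.size == 1:
                for j in plan.subgroups[cg[0]]:
                    if not valid[j]:
                        continue
                    if active_mask is not None and not active_mask[k, j]:
                        continue
                    old = beta[k, j]
                    new = _update_one(data, spec, beta, r, k, j)
                    if new != old:
                        r -= (new - old) * XT[j]
                        beta[k, j] = new
                    rel = abs(new - old) / max(abs(old), _REL_FLOOR)
                    if rel > max_rel:
                        max_rel = rel
                continue
            frozen = r.copy()
            merged: list[tuple[int, float]] = []
            for h in cg:
                rp = frozen.copy()
                for j in plan.subgroups[h]:
                    if not valid[j]:
                        continue
                    if active_mask is not None and not active_mask[k, j]:
                        continue
                    old = beta[k, j]
                    new = _update_one(data, spec, beta, rp, k, j)
                    if new != old:
                        rp -= (new - old) * XT[j]
                        beta[k, j] = new
                        merged.append((j, new - old))
                    rel = abs(new - old) / max(abs(old), _REL_FLOOR)
                    if rel > max_rel:
                        max_rel = rel
            for j, delta in merged:
                r -= delta * XT[j]
    return max_rel


def blocked_fit(
    data: FitData,
    spec: PenaltySpec,
    plan: PartitionPlan,
    init: CoefficientState | None = None,
    tol: float = 1e-3,
    max_cycles: int = 10_000,
) -> CoefficientState:
    """Coordinate descent under the blocked-update schedule.

    Convergence uses the same rule as :func:`ctpr.solver.fit` (max
    relative change over a full blocked cycle < tol), with active-set
    iteration between full cycles. Non-convergence is more likely at
    small s (many simultaneous updates); the warning suggests raising s.
    """
    if plan.n_snps != data.P:
        raise ValueError(f"plan covers {plan.n_snps} SNPs, data has {data.P}")
    state = zero_state(data) if init is None else init.copy()
    beta, residuals = state.beta, state.residuals

    def sweep(mask):
        return _blocked_sweep(data, spec, beta, residuals, plan, mask)

    n_cycles, converged, last = _converge(sweep, beta, tol, max_cycles)
    state.n_cycles += n_cycles
    state.converged = converged
    state.max_rel_change = last
    if not converged:
        warnings.warn(
            f"blocked coordinate descent did not converge in {max_cycles} cycles "
            f"(last max relative change {last:.3g}); consider increasing the number "
            f"of core-groups s (currently {plan.s})",
            stacklevel=2,
        )
    return state
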