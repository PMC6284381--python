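"""Clone phylogenies: simulation, relapse evolution and engraftment.

A leukemia sample is modelled as a rooted tree of clones. Every clone owns a
cell fraction (the proportion of tumor cells belonging to the clone or any of
its descendants), so nesting constraints apply: a clone's fraction never
exceeds its parent's, and sibling fractions sum to at most the parent's
fraction. Somatic mutations are assigned to exactly one clone each; under a
heterozygous-diploid model a mutation's expected allele frequency in a sample
with blast content ``b`` is ``0.5 * b * cell_fraction``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Clone",
    "ClonePhylogeny",
    "simulate_clone_tree",
    "simulate_relapse",
    "simulate_engraftment",
]


@dataclass
class Clone:
    clone_id: str
    parent_id: str | None
    cell_fraction: float


@dataclass
class ClonePhylogeny:
    """A clone tree with per-clone cell fractions and mutation assignments."""

    clones: list[Clone]
    mutation_assignment: dict[str, str]
    founder_id: str

    def clone_map(self) -> dict[str, Clone]:
        return {c.clone_id: c for c in self.clones}

    def children(self, clone_id: str) -> list[Clone]:
        return [c for c in self.clones if c.parent_id == clone_id]

    def mutations_of(self, clone_id: str) -> list[str]:
        return [m for m, c in self.mutation_assignment.items() if c == clone_id]

    def mutation_fractions(self) -> dict[str, float]:
        """Cell fraction carried by each mutation (its clone's fraction)."""
        cmap = self.clone_map()
        return {
            m: cmap[c].cell_fraction for m, c in self.mutation_assignment.items()
        }

    def clonal_mutations(self, min_cell_fraction: float = 0.60) -> set[str]:
        """Mutations carried by clones at or above ``min_cell_fraction``."""
        fr = self.mutation_fractions()
        return {m for m, f in fr.items() if f >= min_cell_fraction}

    def validate(self) -> None:
        cmap = self.clone_map()
        if len(cmap) != len(self.clones):
            raise ValueError("duplicate clone ids")
        founders = [c for c in self.clones if c.parent_id is None]
        if len(founders) != 1 or founders[0].clone_id != self.founder_id:
            raise ValueError("phylogeny must have exactly one founder clone")
        for c in self.clones:
            if not 0.0 <= c.cell_fraction <= 1.0 + 1e-9:
                raise ValueError(f"cell fraction out of range for {c.clone_id}")
            if c.parent_id is not None:
                parent = cmap.get(c.parent_id)
                if parent is None:
                    raise ValueError(f"unknown parent {c.parent_id}")
                if c.cell_fraction > parent.cell_fraction + 1e-9:
                    raise ValueError(
                        f"clone {c.clone_id} exceeds its parent's cell fraction"
                    )
        for cid in cmap:
            sib_sum = sum(ch.cell_fraction for ch in self.children(cid))
            if sib_sum > cmap[cid].cell_fraction + 1e-9:
                raise ValueError(f"children of {cid} exceed parent fraction")
        for mut, cid in self.mutation_assignment.items():
            if cid not in cmap:
                raise ValueError(f"mutation {mut} assigned to unknown clone {cid}")

    def copy(self) -> "ClonePhylogeny":
        return copy.deepcopy(self)


def _available_budget(phylo: ClonePhylogeny, clone_id: str) -> float:
    cmap = phylo.clone_map()
    return cmap[clone_id].cell_fraction - sum(
        c.cell_fraction for c in phylo.children(clone_id)
    )


def simulate_clone_tree(
    n_clones: int, n_mutations: int, seed: int
) -> ClonePhylogeny:
    """Draw a random clone tree with ``n_clones`` clones and ``n_mutations``
    mutations.

    The founder has cell fraction 1.0; each additional clone attaches to a
    random existing clone, taking a uniform share of the parent's remaining
    fraction budget so that nesting constraints hold by construction. Every
    clone carries at least one mutation.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if n_mutations < n_clones:
        raise ValueError("n_mutations must be >= n_clones")
    rng = np.random.default_rng(seed)
    clones = [Clone("C0", None, 1.0)]
    phylo = ClonePhylogeny(clones, {}, "C0")
    for i in range(1, n_clones):
        budgets = np.array(
            [_available_budget(phylo, c.clone_id) for c in phylo.clones]
        )
        budgets = np.clip(budgets, 0.0, None)
        if budgets.sum() <= 1e-6:
            parent = phylo.clones[int(rng.integers(len(phylo.clones)))]
            frac = 0.0
        else:
            probs = budgets / budgets.sum()
            parent = phylo.clones[int(rng.choice(len(phylo.clones), p=probs))]
            frac = _available_budget(phylo, parent.clone_id) * rng.uniform(0.3, 0.9)
        phylo.clones.append(Clone(f"C{i}", parent.clone_id, float(frac)))
    # one mutation per clone, remainder spread uniformly
    mut_ids = [f"M{i:04d}" for i in range(n_mutations)]
    for clone, mut in zip(phylo.clones, mut_ids[:n_clones]):
        phylo.mutation_assignment[mut] = clone.clone_id
    clone_ids = [c.clone_id for c in phylo.clones]
    for mut in mut_ids[n_clones:]:
        phylo.mutation_assignment[mut] = clone_ids[
            int(rng.integers(len(clone_ids)))
        ]
    phylo.validate()
    return phylo


def _scale_non_founder(phylo: ClonePhylogeny, factor: float) -> None:
    for c in phylo.clones:
        if c.parent_id is not None:
            c.cell_fraction *= factor


def simulate_relapse(
    phylo: ClonePhylogeny,
    relapse_type: int,
    n_gained: int,
    seed: int,
    clonal_cell_fraction: float = 0.60,
    gained_prefix: str = "G",
) -> ClonePhylogeny:
    """Evolve an initial-diagnosis phylogeny into a relapse phylogeny.

    Type 1 keeps every initial mutation and adds ``n_gained`` new mutations on
    an expanding relapse subclone. Type 2 additionally loses a non-empty
    proper subset of the initial clonal mutations: the relapse expands from an
    ancestral branch that predates those mutations (bulk sequencing had called
    them clonal because their sub-lineage dominated at diagnosis).
    """
    if relapse_type not in (1, 2):
        raise ValueError("relapse_type must be 1 or 2")
    phylo.validate()
    rng = np.random.default_rng(seed)
    rel = phylo.copy()

    existing = {m for m in rel.mutation_assignment}
    gained = []
    i = 0
    while len(gained) < n_gained:
        mid = f"{gained_prefix}{i:04d}"
        if mid not in existing:
            gained.append(mid)
        i += 1

    # the relapse clone expands under the founder, squeezing prior clones
    f_new = rng.uniform(0.30, 0.50)
    _scale_non_founder(rel, 1.0 - f_new)
    new_id = "RC0"
    while new_id in {c.clone_id for c in rel.clones}:
        new_id = "RC" + str(int(new_id[2:]) + 1)
    rel.clones.append(Clone(new_id, rel.founder_id, f_new))
    for mid in gained:
        rel.mutation_assignment[mid] = new_id

    if relapse_type == 2:
        clonal = sorted(
            m
            for m in phylo.clonal_mutations(clonal_cell_fraction)
            if m in rel.mutation_assignment
        )
        if len(clonal) >= 2:
            k_loss = int(rng.integers(1, min(3, len(clonal) - 1) + 1))
        else:
            k_loss = 1 if clonal else 0
        lost = rng.choice(clonal, size=min(k_loss, len(clonal)), replace=False)
        for mid in lost:
            del rel.mutation_assignment[str(mid)]
    rel.validate()
    return rel


def _enforce_nesting(phylo: ClonePhylogeny) -> None:
    """Top-down repair: cap children at the parent fraction, scale sibling
    groups that overflow the parent's budget."""
    cmap = phylo.clone_map()
    order = [phylo.founder_id]
    i = 0
    while i < len(order):
        for ch in phylo.children(order[i]):
            order.append(ch.clone_id)
        i += 1
    for cid in order:
        parent = cmap[cid]
        kids = phylo.children(cid)
        for ch in kids:
            ch.cell_fraction = min(ch.cell_fraction, parent.cell_fraction)
        total = sum(ch.cell_fraction for ch in kids)
        if total > parent.cell_fraction and total > 0:
            f = parent.cell_fraction / total
            for ch in kids:
                ch.cell_fraction *= f


def _drop_subtree(phylo: ClonePhylogeny, clone_id: str) -> None:
    to_drop = {clone_id}
    changed = True
    while changed:
        changed = False
        for c in phylo.clones:
            if c.parent_id in to_drop and c.clone_id not in to_drop:
                to_drop.add(c.clone_id)
                changed = True
    phylo.clones = [c for c in phylo.clones if c.clone_id not in to_drop]
    phylo.mutation_assignment = {
        m: c for m, c in phylo.mutation_assignment.items() if c not in to_drop
    }


def _amplify_clone(phylo: ClonePhylogeny, clone_id: str, target: float) -> None:
    """Raise ``clone_id`` (and its ancestors as needed) to ``target`` cell
    fraction, scaling competing siblings down to preserve nesting."""
    cmap = phylo.clone_map()
    path = [clone_id]
    while cmap[path[-1]].parent_id is not None:
        path.append(cmap[path[-1]].parent_id)
    for cid in path[:-1]:
        cmap[cid].cell_fraction = max(cmap[cid].cell_fraction, target)
    cmap[clone_id].cell_fraction = target
    path_set = set(path)
    for cid in reversed(path):  # founder first
        parent = cmap[cid]
        kids = phylo.children(cid)
        on_path = [k for k in kids if k.clone_id in path_set]
        off_path = [k for k in kids if k.clone_id not in path_set]
        budget = parent.cell_fraction - sum(k.cell_fraction for k in on_path)
        total_off = sum(k.cell_fraction for k in off_path)
        if total_off > budget and total_off > 0:
            f = max(budget, 0.0) / total_off
            for k in off_path:
                k.cell_fraction *= f
    _enforce_nesting(phylo)


def simulate_engraftment(
    phylo: ClonePhylogeny,
    mode: str,
    config,
    seed: int,
    hidden_prefix: str = "X",
) -> ClonePhylogeny:
    """Transform a patient phylogeny into the engrafted (PDX) phylogeny.

    Mode A preserves every clone, jittering cell fractions by at most the
    configured tolerance. Mode B remodels the architecture by one of three
    selection events, mirroring the patterns seen in real xenografts:

    * a mid-size subclone is eradicated together with its descendants,
    * a small subclone is amplified to near-dominance (>= 2-fold expansion),
    * a clone that was below the detection limit in the patient rises above
      it, appearing as a cluster of PDX-specific variants.

    In mode B, small subclones are additionally lost at random with the
    configured size-dependent loss probability.
    """
    if mode not in ("A", "B"):
        raise ValueError("mode must be 'A' or 'B'")
    phylo.validate()
    rng = np.random.default_rng(seed)
    pdx = phylo.copy()

    if mode == "A":
        tol = config.mode_a_fraction_tolerance
        for c in pdx.clones:
            if c.parent_id is not None:
                c.cell_fraction = float(
                    np.clip(c.cell_fraction * (1.0 + rng.uniform(-tol, tol)), 0, 1)
                )
        _enforce_nesting(pdx)
        pdx.validate()
        return pdx

    # mode B: pick a feasible remodeling action
    counts = {c.clone_id: 0 for c in pdx.clones}
    for cid in pdx.mutation_assignment.values():
        counts[cid] += 1
    droppable = [
        c.clone_id
        for c in pdx.clones
        if c.parent_id is not None
        and 0.40 <= c.cell_fraction < 0.60
        and counts[c.clone_id] >= 3
    ]
    amplifiable = [
        c.clone_id
        for c in pdx.clones
        if c.parent_id is not None
        and c.cell_fraction <= 0.30
        and counts[c.clone_id] >= 1
    ]
    actions = ["hidden_rise"]
    if droppable:
        actions.append("drop")
    if amplifiable:
        actions.append("amplify")
    action = actions[int(rng.integers(len(actions)))]

    if action == "drop":
        _drop_subtree(pdx, droppable[int(rng.integers(len(droppable)))])
    elif action == "amplify":
        target = float(rng.uniform(0.80, 0.95))
        _amplify_clone(pdx, amplifiable[int(rng.integers(len(amplifiable)))], target)
    else:  # hidden_rise
        n_new = int(rng.integers(2, 5))
        existing = set(pdx.mutation_assignment)
        new_muts, i = [], 0
        while len(new_muts) < n_new:
            mid = f"{hidden_prefix}{i:04d}"
            if mid not in existing:
                new_muts.append(mid)
            i += 1
        frac = float(rng.uniform(0.80, 0.95))
        new_id = "XC0"
        while new_id in {c.clone_id for c in pdx.clones}:
            new_id = "XC" + str(int(new_id[2:]) + 1)
        _scale_non_founder(pdx, 1.0 - frac)
        pdx.clones.append(Clone(new_id, pdx.founder_id, frac))
        for mid in new_muts:
            pdx.mutation_assignment[mid] = new_id

    # stochastic loss of small subclones
    for c in list(pdx.clones):
        if c.parent_id is None or c.clone_id not in {
            x.clone_id for x in pdx.clones
        }:
            continue
        p_loss = float(config.subclone_loss_probability(c.cell_fraction))
        if rng.uniform() < p_loss:
            _drop_subtree(pdx, c.clone_id)

    _enforce_nesting(pdx)
    pdx.validate()
    return pdx
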