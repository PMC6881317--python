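"""Codon-sequence simulation along phylogenies with known truth.

Emulates desk-scale retrogene-pair data: Oryza-like trees (6-16 tips,
branch depths of order 0.01-0.2 substitutions per codon), 150-600 codons,
background omega around 0.1-0.4, and episodic omega >= 1 on chosen
branches, including branch-site structure where a small fraction of sites
is under positive selection on a foreground branch.

Sequences evolve by exact jump-chain (Gillespie) sampling of the
continuous-time codon chain, so the truth record carries the *realised*
per-branch synonymous and non-synonymous substitution counts, not just
expectations.  All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .genetic_code import AA_ARRAY, N_STATES, SENSE_CODONS
from .codon_model import _generator, substitution_rate
from .seq_tree_io import CodonAlignment, GAP_CODON, PhyloTree, TreeNode

# Study-scale defaults: background purifying selection typical of rice
# coding genes, transition bias ~2, desk-scale gene lengths.
DEFAULT_KAPPA = 2.0
DEFAULT_BACKGROUND_OMEGA = 0.2
DEFAULT_FOREGROUND_OMEGA = 4.0
DEFAULT_N_CODONS = 500
BRANCH_LENGTH_RANGE = (0.02, 0.10)  # substitutions per codon


@dataclass
class SimulationConfig:
    tree: PhyloTree
    n_codons: int = DEFAULT_N_CODONS
    kappa: float = DEFAULT_KAPPA
    omega_scheme: dict[str, Any] = field(
        default_factory=lambda: {"type": "one_ratio", "omega": DEFAULT_BACKGROUND_OMEGA}
    )
    freqs: np.ndarray | None = None  # None -> uniform over sense codons
    seed: int = 0
    gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must be in [0, 1)")


def _is_synonymous(i: int, j: int) -> bool:
    return AA_ARRAY[i] == AA_ARRAY[j]


class _JumpSampler:
    """Jump-chain sampler for one scaled generator.

    Branch-wise schemes self-scale (branch lengths in substitutions per
    codon at that branch's omega); branch-site schemes pass the shared
    mixture scale so fast site classes really substitute faster.
    """

    def __init__(
        self, freqs: np.ndarray, kappa: float, omega: float, scale: float | None = None
    ):
        q = _generator(freqs, kappa, omega)
        if scale is None:
            scale = -float(np.dot(freqs, np.diag(q)))
        q /= scale
        self.exit_rate = -np.diag(q).copy()
        jump = q.copy()
        np.fill_diagonal(jump, 0.0)
        rows = jump.sum(axis=1, keepdims=True)
        # absorbing states (e.g. Met/Trp at omega = 0) have no exits
        rows[rows == 0.0] = 1.0
        self.jump_probs = jump / rows
        self.jump_cum = np.cumsum(self.jump_probs, axis=1)

    def evolve(self, state: int, t: float, rng: np.random.Generator):
        """Return (end state, n_nonsyn, n_syn) after time t."""
        n_n = n_s = 0
        clock = 0.0
        while True:
            if self.exit_rate[state] <= 0.0:
                return state, n_n, n_s
            clock += rng.exponential(1.0 / self.exit_rate[state])
            if clock >= t:
                return state, n_n, n_s
            nxt = int(np.searchsorted(self.jump_cum[state], rng.random()))
            if _is_synonymous(state, nxt):
                n_s += 1
            else:
                n_n += 1
            state = nxt


def _site_omegas(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-branch, per-site omega assignment plus the truth site classes.

    Returns (omega_of_branch_site: branch_id -> array of omega per site,
    site_class array or None).  Site classes follow the branch-site
    construction: a site's class is drawn once at the root and is a
    property of the site, not the branch.
    """
    scheme = cfg.omega_scheme
    kind = scheme["type"]
    n = cfg.n_codons
    branch_ids = [b.branch_id for b in cfg.tree.branches]

    if kind == "one_ratio":
        w = float(scheme["omega"])
        return {b: np.full(n, w) for b in branch_ids}, None

    if kind == "branch":
        bg = float(scheme.get("background", DEFAULT_BACKGROUND_OMEGA))
        table = {int(k): float(v) for k, v in scheme["omega_of_branch"].items()}
        return {b: np.full(n, table.get(b, bg)) for b in branch_ids}, None

    if kind == "planted_sites":
        bg = float(scheme.get("background", DEFAULT_BACKGROUND_OMEGA))
        w2 = float(scheme["omega2"])
        fg = set(scheme["foreground"])
        sites = np.asarray(sorted(scheme["sites"]), dtype=int)
        if sites.size and (sites.min() < 0 or sites.max() >= n):
            raise ValueError("planted site index out of range")
        bg_omega = np.full(n, bg)
        fg_omega = np.full(n, bg)
        fg_omega[sites] = w2
        classes = np.zeros(n, dtype=int)
        classes[sites] = 2
        return (
            {b: (fg_omega if b in fg else bg_omega).copy() for b in branch_ids},
            classes,
        )

    if kind == "branch_site":
        p0, p1 = float(scheme["p0"]), float(scheme["p1"])
        w0, w2 = float(scheme["omega0"]), float(scheme["omega2"])
        fg = set(scheme["foreground"])
        p2 = 1.0 - p0 - p1
        if p2 < -1e-9:
            raise ValueError("branch-site proportions exceed 1")
        denom = p0 + p1 if p0 + p1 > 0 else 1.0
        probs = [p0, p1, max(p2, 0.0) * p0 / denom, max(p2, 0.0) * p1 / denom]
        probs = np.array(probs) / np.sum(probs)
        classes = rng.choice(4, size=n, p=probs)
        bg_omega = np.choose(classes, [w0, 1.0, w0, 1.0])
        fg_omega = np.choose(classes, [w0, 1.0, w2, w2])
        return (
            {b: (fg_omega if b in fg else bg_omega).copy() for b in branch_ids},
            classes,
        )

    raise ValueError(f"unknown omega scheme {kind!r}")


def simulate_alignment(cfg: SimulationConfig) -> tuple[CodonAlignment, dict]:
    """Evolve codons down the tree; return alignment plus truth record.

    The truth record holds the per-branch realised (nN, nS) counts, the
    per-site omega classes for branch-site schemes, the root sequence and
    the generating parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = (
        np.full(N_STATES, 1.0 / N_STATES) if cfg.freqs is None else np.asarray(cfg.freqs)
    )
    omega_site, site_classes = _site_omegas(cfg, rng)

    # branch-site schemes share one scale across site classes (the
    # mixture-averaged background rate), matching the fitted model
    shared_scale = None
    if cfg.omega_scheme["type"] == "planted_sites":
        bg = float(cfg.omega_scheme.get("background", DEFAULT_BACKGROUND_OMEGA))
        shared_scale = substitution_rate(freqs, cfg.kappa, bg)
    elif cfg.omega_scheme["type"] == "branch_site":
        s = cfg.omega_scheme
        p0, p1 = float(s["p0"]), float(s["p1"])
        w0 = float(s["omega0"])
        rest = max(1.0 - p0 - p1, 0.0)
        denom = p0 + p1 if p0 + p1 > 0 else 1.0
        wt0 = p0 + rest * p0 / denom
        wt1 = p1 + rest * p1 / denom
        shared_scale = wt0 * substitution_rate(freqs, cfg.kappa, w0) + (
            wt1 * substitution_rate(freqs, cfg.kappa, 1.0)
        )

    samplers: dict[float, _JumpSampler] = {}

    def sampler(w: float) -> _JumpSampler:
        if w not in samplers:
            samplers[w] = _JumpSampler(freqs, cfg.kappa, w, shared_scale)
        return samplers[w]

    root_states = rng.choice(N_STATES, size=cfg.n_codons, p=freqs)
    states: dict[int, np.ndarray] = {}
    counts: dict[int, tuple[float, float]] = {}

    order = cfg.tree.postorder()
    for node in reversed(order):  # pre-order: parents before children
        if node is cfg.tree.root:
            states[id(node)] = root_states
            continue
        parent_states = states[id(node.parent)]
        omegas = omega_site[node.branch_id]
        out = np.empty(cfg.n_codons, dtype=np.int64)
        n_n = n_s = 0
        for s in range(cfg.n_codons):
            end, dn, ds = sampler(float(omegas[s])).evolve(
                int(parent_states[s]), node.length, rng
            )
            out[s] = end
            n_n += dn
            n_s += ds
        states[id(node)] = out
        counts[node.branch_id] = (float(n_n), float(n_s))

    leaves = cfg.tree.leaves()
    codon_array = np.array(SENSE_CODONS)
    mat = np.array([codon_array[states[id(n)]] for n in leaves], dtype="<U3")
    taxa = [n.name for n in leaves]

    gap_columns: list[int] = []
    if cfg.gap_fraction > 0:
        n_gap = int(round(cfg.gap_fraction * cfg.n_codons))
        gap_columns = sorted(
            rng.choice(cfg.n_codons, size=n_gap, replace=False).tolist()
        )
        for j in gap_columns:
            rows = rng.choice(len(taxa), size=rng.integers(1, len(taxa)), replace=False)
            for r in rows:
                mat[r, j] = GAP_CODON

    truth = {
        "counts": counts,
        "site_classes": site_classes,
        "root_states": root_states,
        "gap_columns": gap_columns,
        "kappa": cfg.kappa,
        "omega_scheme": cfg.omega_scheme,
        "seed": cfg.seed,
    }
    return CodonAlignment(taxa, mat), truth


# ---------------------------------------------------------------------------
# tree shapes and fixtures
# ---------------------------------------------------------------------------


def clade_branch_set(tree: PhyloTree, stem_branch_id: int) -> set[int]:
    """The stem branch plus every branch inside the subtended clade."""
    out = [stem_branch_id]
    stack = [tree.branch(stem_branch_id)]
    while stack:
        node = stack.pop()
        for ch in node.children:
            out.append(ch.branch_id)
            stack.append(ch)
    return set(out)


def pick_foreground_clade(
    tree: PhyloTree, rng: np.random.Generator, leaf_range: tuple[int, int] = (4, 5)
) -> set[int]:
    """A foreground branch set: an internal clade of the requested size.

    Root-incident branches are avoided (their lengths pool under the
    reversible model); falls back to 3-leaf clades on topologies without
    a clade in the requested range.
    """
    root_children = {ch.branch_id for ch in tree.root.children}
    lo, hi = leaf_range

    def candidates(a, b):
        return [
            br.branch_id
            for br in tree.branches
            if not br.is_leaf
            and br.branch_id not in root_children
            and a <= len(tree.subtended_leaves(br.branch_id)) <= b
        ]

    cands = candidates(lo, hi) or candidates(3, hi)
    if not cands:
        raise ValueError("no internal clade of suitable size in this tree")
    stem = cands[int(rng.integers(len(cands)))]
    return clade_branch_set(tree, stem)


def make_branch_site_fixture(
    scenario: str,
    seed: int,
    n_tips: int = 10,
    n_codons: int = 400,
    omega0: float = 0.02,
    omega2: float = 10.0,
    p0: float = 0.85,
    p1: float = 0.05,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[CodonAlignment, PhyloTree, dict]:
    """Branch-site calibration fixtures with a clade foreground.

    ``null``: M1a-style data (conserved + neutral site classes, no
    selected class) for type-I-error calibration of test 1.
    ``selected``: Model A data with a fraction 1 - p0 - p1 of sites under
    omega2 on the foreground clade, for power checks.
    The foreground is a whole retrocopy-like clade (stem plus descendant
    branches) so that foreground substitutions are witnessed by several
    lineages — the regime in which the branch-site machinery is used here.
    """
    if scenario not in ("null", "selected"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    tree = random_tree(n_tips, rng, length_range=(0.04, 0.10))
    foreground = pick_foreground_clade(tree, rng)
    if scenario == "null":
        z = p0 + p1
        scheme = {
            "type": "branch_site",
            "p0": p0 / z,
            "p1": p1 / z,
            "omega0": omega0,
            "omega2": 1.0,
            "foreground": foreground,
        }
    else:
        scheme = {
            "type": "branch_site",
            "p0": p0,
            "p1": p1,
            "omega0": omega0,
            "omega2": omega2,
            "foreground": foreground,
        }
    cfg = SimulationConfig(
        tree=tree,
        n_codons=n_codons,
        kappa=kappa,
        omega_scheme=scheme,
        seed=int(rng.integers(2**31 - 1)),
    )
    aln, truth = simulate_alignment(cfg)
    truth["foreground"] = foreground
    tree.set_foreground(foreground)
    return aln, tree, truth


def make_beb_fixture(
    seed: int,
    n_tips: int = 10,
    n_codons: int = 400,
    n_planted: int = 5,
    background_omega: float = 0.02,
    omega2: float = 10.0,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[CodonAlignment, PhyloTree, dict]:
    """Site-recovery fixture: a few strongly selected foreground sites.

    Plants ``n_planted`` sites with omega2 on a foreground clade in an
    otherwise strongly conserved gene (background omega matching the
    near-zero omega0 estimates typical of parental genes), the regime in
    which empirical-Bayes site identification is informative.
    """
    rng = np.random.default_rng(seed)
    tree = random_tree(n_tips, rng, length_range=(0.04, 0.10))
    foreground = pick_foreground_clade(tree, rng)
    planted = sorted(int(s) for s in rng.choice(n_codons, size=n_planted, replace=False))
    cfg = SimulationConfig(
        tree=tree,
        n_codons=n_codons,
        kappa=kappa,
        omega_scheme={
            "type": "planted_sites",
            "background": background_omega,
            "omega2": omega2,
            "foreground": foreground,
            "sites": planted,
        },
        seed=int(rng.integers(2**31 - 1)),
    )
    aln, truth = simulate_alignment(cfg)
    truth["foreground"] = foreground
    truth["planted_sites"] = planted
    tree.set_foreground(foreground)
    return aln, tree, truth


# ---------------------------------------------------------------------------
# retrogene-pair fixtures
# ---------------------------------------------------------------------------


def random_tree(
    n_tips: int,
    rng: np.random.Generator,
    length_range: tuple[float, float] = BRANCH_LENGTH_RANGE,
    labels: list[str] | None = None,
) -> PhyloTree:
    """Random rooted binary topology with uniform branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    labels = labels or [f"t{i + 1}" for i in range(n_tips)]
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = PhyloTree(nodes[0])
    lo, hi = length_range
    for b in tree.branches:
        b.length = float(rng.uniform(lo, hi))
    return tree


def _clade(labels: list[str], suffix: str, rng, length_range) -> TreeNode:
    sub = random_tree(
        len(labels), rng, length_range, [f"{lab}_{suffix}" for lab in labels]
    )
    return sub.root


def make_pair_fixture(
    scenario: str,
    seed: int,
    n_species: int = 3,
    n_codons: int = DEFAULT_N_CODONS,
    background_omega: float = DEFAULT_BACKGROUND_OMEGA,
    foreground_omega: float = DEFAULT_FOREGROUND_OMEGA,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[CodonAlignment, PhyloTree, dict]:
    """Retrogene-pair fixture with a known selected branch.

    A duplication node joins a parental clade (``*_P`` leaves) and a
    retrocopy clade (``*_C``); an outgroup parental copy (``out_P``, a
    lineage that diverged before the retroposition) sits outside the
    duplication clade so that the two stems incident to the duplication
    node are identifiable under the reversible model.  Scenarios place
    omega > 1 on: the young retrocopy stem (``pattern1``), the parental
    stem immediately after the duplication (``pattern2``), a later
    parental-lineage branch (``pattern3``), or nowhere (``null``).
    """
    if scenario not in ("pattern1", "pattern2", "pattern3", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    parental = _clade(species, "P", rng, BRANCH_LENGTH_RANGE)
    retro = _clade(species, "C", rng, BRANCH_LENGTH_RANGE)
    dup = TreeNode(children=[parental, retro])
    outgroup = TreeNode(name="out_P")
    root = TreeNode(children=[outgroup, dup])
    tree = PhyloTree(root)
    # stem branches span the whole pre-speciation period after the
    # duplication, so they run longer than within-clade branches
    for extra in (parental, retro, dup, outgroup):
        extra.length = float(rng.uniform(0.06, 0.12))

    parental_taxa = {f"{s}_P" for s in species}
    retro_taxa = {f"{s}_C" for s in species}

    def branch_of(node: TreeNode) -> int:
        return node.branch_id

    selected: list[int] = []
    if scenario == "pattern1":
        selected = [branch_of(retro)]
    elif scenario == "pattern2":
        selected = [branch_of(parental)]
    elif scenario == "pattern3":
        # a parental-side branch not incident to the duplication node
        candidates = [
            b.branch_id
            for b in tree.branches
            if tree.subtended_leaves(b.branch_id) < parental_taxa
            and b.parent is not parental.parent
        ]
        inner = [
            b for b in candidates if not tree.branch(b).is_leaf
        ] or candidates
        selected = [inner[int(rng.integers(len(inner)))]]

    scheme: dict[str, Any]
    if selected:
        scheme = {
            "type": "branch",
            "background": background_omega,
            "omega_of_branch": {b: foreground_omega for b in selected},
        }
    else:
        scheme = {"type": "one_ratio", "omega": background_omega}

    cfg = SimulationConfig(
        tree=tree,
        n_codons=n_codons,
        kappa=kappa,
        omega_scheme=scheme,
        seed=int(rng.integers(2**31 - 1)),
    )
    aln, truth = simulate_alignment(cfg)
    truth.update(
        {
            "scenario": scenario,
            "positive_branches": selected,
            "parental_taxa": sorted(parental_taxa),
            "retro_taxa": sorted(retro_taxa),
            "background_omega": background_omega,
            "foreground_omega": foreground_omega,
        }
    )
    tree.set_foreground(selected)
    return aln, tree, truth
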