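"""Sequence evolution down a species tree.

Four generating processes are supported: neutral HKY85, rate-scaled
("conserved") HKY85, MG94 codon evolution, and a structured-RNA process in
which paired positions substitute jointly (compensatory) and the whole
structure can be lost on a branch, after which positions evolve neutrally.
Substitution uses exact transition matrices from the model's spectral
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..annotation_io.trees import SpeciesTree
from ..coding_potential.models import (
    NUCLEOTIDES,
    SENSE_CODONS,
    SubstitutionModel,
    hky_model,
    mg94_model,
)

DEFAULT_PI = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class NeutralSpec:
    kappa: float = 2.5
    scale: float = 1.0
    pi: tuple = DEFAULT_PI


@dataclass(frozen=True)
class ConservedSpec:
    r: float = 0.2  # rate multiplier < 1
    kappa: float = 2.5
    scale: float = 1.0
    pi: tuple = DEFAULT_PI


@dataclass(frozen=True)
class CodingSpec:
    omega: float = 0.1
    kappa: float = 2.5
    scale: float = 1.0
    pi: tuple = DEFAULT_PI


@dataclass(frozen=True)
class StructuredSpec:
    """``pairs`` are (i, j) offsets within the simulated segment."""

    pairs: tuple = ()
    compensatory_prob: float = 0.9
    decay_rate: float = 0.0       # structure-loss rate per unit branch length
    pair_sub_rate: float = 0.8    # joint substitution events per pair per unit length
    kappa: float = 2.5
    scale: float = 1.0
    pi: tuple = DEFAULT_PI


# complementary pairs a retained stem may hold, with sampling weights
_PAIR_CHOICES = ["GC", "CG", "AT", "TA", "GT", "TG"]
_PAIR_WEIGHTS = np.array([0.35, 0.35, 0.10, 0.10, 0.05, 0.05])


def _sample_states(pi: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(len(pi), size=length, p=pi)


def _evolve_states(
    states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One branch of CTMC evolution given transition matrix P."""
    C = np.cumsum(P, axis=1)
    u = rng.random(len(states))
    return (u[:, None] > C[states]).sum(axis=1)


def _leaf_sequences(
    tree: SpeciesTree,
    model: SubstitutionModel,
    scale: float,
    length: int,
    rng: np.random.Generator,
    alphabet: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Evolve ``length`` iid sites; returns per-leaf state arrays."""
    root_states = _sample_states(model.pi, length, rng)
    states = {tree.root: root_states}
    out: dict[str, np.ndarray] = {}
    for node in reversed(tree.nodes):  # preorder
        cur = states[node.index]
        if node.is_leaf and node.index != tree.root:
            out[node.name] = cur
        for ci in node.children:
            child = tree.nodes[ci]
            P = model.transition_matrix(child.branch_length * scale)
            states[ci] = _evolve_states(cur, P, rng)
            if child.is_leaf:
                out[child.name] = states[ci]
    return out


def _nt_decode(states: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[s] for s in states)


def _codon_decode(states: np.ndarray) -> str:
    return "".join(SENSE_CODONS[s] for s in states)


def simulate_neutral(
    tree: SpeciesTree, spec: NeutralSpec, length: int, rng: np.random.Generator
) -> dict[str, str]:
    model = hky_model(np.array(spec.pi), spec.kappa)
    leaves = _leaf_sequences(tree, model, spec.scale, length, rng, tuple(NUCLEOTIDES))
    return {sp: _nt_decode(st) for sp, st in leaves.items()}


def simulate_conserved(
    tree: SpeciesTree, spec: ConservedSpec, length: int, rng: np.random.Generator
) -> dict[str, str]:
    model = hky_model(np.array(spec.pi), spec.kappa)
    leaves = _leaf_sequences(tree, model, spec.scale * spec.r, length, rng, tuple(NUCLEOTIDES))
    return {sp: _nt_decode(st) for sp, st in leaves.items()}


def simulate_coding(
    tree: SpeciesTree, spec: CodingSpec, n_codons: int, rng: np.random.Generator
) -> dict[str, str]:
    model = mg94_model(np.array(spec.pi), spec.kappa, spec.omega)
    leaves = _leaf_sequences(tree, model, spec.scale, n_codons, rng, SENSE_CODONS)
    return {sp: _codon_decode(st) for sp, st in leaves.items()}


def simulate_frozen(tree: SpeciesTree, sequence: str) -> dict[str, str]:
    """All leaves identical (invariant positions such as planted start/stop)."""
    return {name: sequence for name in tree.leaf_names}


def simulate_structured(
    tree: SpeciesTree,
    spec: StructuredSpec,
    length: int,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, bool]]:
    """Structured-RNA evolution; returns leaf sequences and per-leaf
    structure-retention flags."""
    model = hky_model(np.array(spec.pi), spec.kappa)
    paired_idx = sorted({i for p in spec.pairs for i in p})
    paired_set = set(paired_idx)
    if any(i >= length or j >= length or i >= j for i, j in spec.pairs):
        raise ValueError("structure pairs out of range")
    seq = _sample_states(np.asarray(model.pi), length, rng)
    for i, j in spec.pairs:
        choice = rng.choice(len(_PAIR_CHOICES), p=_PAIR_WEIGHTS / _PAIR_WEIGHTS.sum())
        a, b = _PAIR_CHOICES[choice]
        seq[i] = NUCLEOTIDES.index(a)
        seq[j] = NUCLEOTIDES.index(b)

    out_seq: dict[str, str] = {}
    out_kept: dict[str, bool] = {}

    def descend(node_idx: int, states: np.ndarray, lost: bool) -> None:
        node = tree.nodes[node_idx]
        if node.is_leaf:
            out_seq[node.name] = _nt_decode(states)
            out_kept[node.name] = not lost
            return
        for ci in node.children:
            child = tree.nodes[ci]
            t = child.branch_length * spec.scale
            child_states = states.copy()
            child_lost = lost
            if not lost and rng.random() < 1.0 - np.exp(-spec.decay_rate * t):
                child_lost = True
            if child_lost:
                P = model.transition_matrix(t)
                child_states = _evolve_states(child_states, P, rng)
            else:
                unpaired = np.array(
                    [k for k in range(length) if k not in paired_set], dtype=int
                )
                if len(unpaired):
                    P = model.transition_matrix(t)
                    child_states[unpaired] = _evolve_states(child_states[unpaired], P, rng)
                p_event = 1.0 - np.exp(-spec.pair_sub_rate * t)
                for i, j in spec.pairs:
                    if rng.random() >= p_event:
                        continue
                    if rng.random() < spec.compensatory_prob:
                        choice = rng.choice(
                            len(_PAIR_CHOICES), p=_PAIR_WEIGHTS / _PAIR_WEIGHTS.sum()
                        )
                        a, b = _PAIR_CHOICES[choice]
                        child_states[i] = NUCLEOTIDES.index(a)
                        child_states[j] = NUCLEOTIDES.index(b)
                    else:
                        side = i if rng.random() < 0.5 else j
                        child_states[side] = rng.choice(4)
            descend(ci, child_states, child_lost)

    descend(tree.root, seq, False)
    return out_seq, out_kept


def simulate_alignment(
    tree: SpeciesTree,
    model_spec,
    length: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Dispatch on the spec type.

    Returns leaf sequences (dict species -> str); structured specs
    additionally return the per-species retention truth.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(model_spec, NeutralSpec):
        return simulate_neutral(tree, model_spec, length, rng)
    if isinstance(model_spec, ConservedSpec):
        return simulate_conserved(tree, model_spec, length, rng)
    if isinstance(model_spec, CodingSpec):
        if length % 3:
            raise ValueError("coding length must be a codon multiple")
        return simulate_coding(tree, model_spec, length // 3, rng)
    if isinstance(model_spec, StructuredSpec):
        return simulate_structured(tree, model_spec, length, rng)
    raise ValueError(f"unknown model spec {model_spec!r}")


def ladder_tree(newick: str | None = None) -> SpeciesTree:
    """Default 8-species topology: a 6-species ingroup ladder plus a
    2-species outgroup, branch lengths in substitutions/site."""
    if newick is None:
        newick = (
            "((((((ref:0.04,sA:0.04):0.05,sB:0.09):0.09,sC:0.18):0.18,sD:0.36)"
            ":0.18,sE:0.54):0.26,(out1:0.40,out2:0.40):0.40);"
        )
    return SpeciesTree.from_newick(newick)


def hairpin_pairs(offset: int, stem: int = 10, loop: int = 5) -> list[tuple[int, int]]:
    """Pairs of a single hairpin starting at ``offset``."""
    total = 2 * stem + loop
    return [(offset + k, offset + total - 1 - k) for k in range(stem)]
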