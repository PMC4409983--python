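"""Substitution models and the pruning likelihood engine.

Two reversible continuous-time Markov models are provided:

* HKY85 on the four nucleotides (base frequencies ``pi``,
  transition/transversion ratio ``kappa``), unit-scaled so branch lengths
  are expected substitutions per site.
* MG94xHKY on the 61 sense codons (shared ``pi``/``kappa``, a
  nonsynonymous/synonymous rate ratio ``omega``), scaled to an expected
  three nucleotide substitutions per codon per unit branch length so codon
  and nucleotide likelihoods share the same branch-length units under
  neutrality (omega = 1).

Likelihoods are computed by Felsenstein pruning, vectorized over columns,
with per-node rescaling.  Ambiguous characters and gaps contribute partial
vectors of ones (missing data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from ..annotation_io.trees import SpeciesTree

NUCLEOTIDES = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def hky_rate_matrix(pi: np.ndarray, kappa: float) -> np.ndarray:
    """Unit-scaled HKY85 rate matrix (rows sum to zero)."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,) or np.any(pi <= 0):
        raise ValueError("pi must be 4 positive frequencies")
    pi = pi / pi.sum()
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    Q = np.zeros((4, 4))
    for i, a in enumerate(NUCLEOTIDES):
        for j, b in enumerate(NUCLEOTIDES):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if is_transition(a, b) else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    return Q / rate


def codon_stationary(pi: np.ndarray) -> np.ndarray:
    """Stationary distribution over sense codons: product of base frequencies."""
    pi = np.asarray(pi, dtype=float)
    w = np.array(
        [pi[NT_INDEX[c[0]]] * pi[NT_INDEX[c[1]]] * pi[NT_INDEX[c[2]]] for c in SENSE_CODONS]
    )
    return w / w.sum()


def mg94_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> tuple[np.ndarray, np.ndarray]:
    """MG94xHKY rate matrix over 61 sense codons and its stationary vector.

    Scaled to 3 expected nucleotide substitutions per codon per unit branch
    length at omega = 1.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            a, b = ci[k], cj[k]
            rate = pi[NT_INDEX[b]]
            if is_transition(a, b):
                rate *= kappa
            if CODON_AA[ci] != CODON_AA[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    cpi = codon_stationary(pi)
    # calibrate against the neutral (omega=1) flux so omega<1 genuinely slows
    # the chain rather than being renormalized away
    Qn = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            a, b = ci[k], cj[k]
            Qn[i, j] = pi[NT_INDEX[b]] * (kappa if is_transition(a, b) else 1.0)
    np.fill_diagonal(Qn, -Qn.sum(axis=1))
    neutral_rate = -np.dot(cpi, np.diag(Qn))
    Q = Q * (3.0 / neutral_rate)
    return Q, cpi


@dataclass
class SubstitutionModel:
    """A reversible rate matrix with cached spectral decomposition."""

    pi: np.ndarray
    Q: np.ndarray
    name: str = "model"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def _eigen(self):
        if self._eig is None:
            d = np.sqrt(self.pi)
            B = self.Q * d[:, None] / d[None, :]
            B = 0.5 * (B + B.T)  # symmetric up to round-off for reversible Q
            lam, U = np.linalg.eigh(B)
            left = U.T * d[None, :]        # U^T D^{1/2}
            right = U / d[:, None]         # D^{-1/2} U
            self._eig = (lam, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), clipped to non-negative."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        lam, right, left = self._eigen()
        P = (right * np.exp(lam * t)[None, :]) @ left
        return np.clip(P, 0.0, None)


def hky_model(pi, kappa: float) -> SubstitutionModel:
    return SubstitutionModel(pi=np.asarray(pi, float) / np.sum(pi),
                             Q=hky_rate_matrix(pi, kappa), name="HKY85")


def mg94_model(pi, kappa: float, omega: float) -> SubstitutionModel:
    Q, cpi = mg94_rate_matrix(pi, kappa, omega)
    return SubstitutionModel(pi=cpi, Q=Q, name=f"MG94xHKY(omega={omega:g})")


# ---------------------------------------------------------------------------
# Leaf partial likelihoods
# ---------------------------------------------------------------------------

def nucleotide_partials(seq: str) -> np.ndarray:
    """(n_sites, 4) partial-likelihood matrix; non-ACGT rows are all ones."""
    out = np.ones((len(seq), 4))
    for i, c in enumerate(seq):
        j = NT_INDEX.get(c)
        if j is not None:
            out[i] = 0.0
            out[i, j] = 1.0
    return out


def codon_partials(seq: str) -> np.ndarray:
    """(n_codons, 61) partials for a gapless-frame string (length % 3 == 0).

    Codons containing gaps/ambiguity, or stop codons, are missing data.
    """
    n = len(seq) // 3
    out = np.ones((n, 61))
    for i in range(n):
        codon = seq[3 * i : 3 * i + 3]
        j = CODON_INDEX.get(codon)
        if j is not None:
            out[i] = 0.0
            out[i, j] = 1.0
    return out


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def site_log_likelihoods(
    tree: SpeciesTree,
    model: SubstitutionModel,
    leaf_partials: dict[str, np.ndarray],
    rate_scale: float = 1.0,
) -> np.ndarray:
    """Per-column log-likelihoods by Felsenstein pruning.

    ``leaf_partials`` maps leaf names to (n_sites, n_states) arrays; leaves
    missing from the dict contribute missing data (all-ones partials).
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be non-negative")
    sizes = {p.shape[0] for p in leaf_partials.values()}
    if len(sizes) != 1:
        raise ValueError("leaf partials disagree on number of sites")
    n_sites = sizes.pop()
    S = model.n_states
    parts: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_sites)
    for node in tree.nodes:
        if node.is_leaf:
            part = leaf_partials.get(node.name)
            if part is None:
                part = np.ones((n_sites, S))
            parts[node.index] = part
            continue
        acc = np.ones((n_sites, S))
        for ci in node.children:
            child = tree.nodes[ci]
            P = model.transition_matrix(child.branch_length * rate_scale)
            acc = acc * (parts.pop(ci) @ P.T)
        m = acc.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        acc = acc / m[:, None]
        logscale += np.log(m)
        parts[node.index] = acc
    root_part = parts[tree.root]
    site_l = root_part @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(site_l) + logscale


def log_likelihood(
    tree: SpeciesTree,
    model: SubstitutionModel,
    leaf_partials: dict[str, np.ndarray],
    rate_scale: float = 1.0,
    weights: np.ndarray | None = None,
) -> float:
    ll = site_log_likelihoods(tree, model, leaf_partials, rate_scale)
    if weights is not None:
        return float(np.dot(ll, weights))
    return float(ll.sum())


def compress_columns(columns: list[str]) -> tuple[list[str], np.ndarray]:
    """Collapse identical alignment columns; returns (patterns, counts)."""
    counts: dict[str, int] = {}
    for col in columns:
        counts[col] = counts.get(col, 0) + 1
    patterns = list(counts)
    return patterns, np.array([counts[p] for p in patterns], dtype=float)
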