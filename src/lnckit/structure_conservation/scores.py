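"""Window-level structure-conservation evidence.

Each window is summarized by a mean folding-energy z-score against shuffled
sequences and a structure conservation index (SCI), combined through a
logistic link into a probability-like score in [0, 1]; windows scoring
above 0.5 are called high-confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ..annotation_io.maf import GAP, RegionAlignment
from .fold import consensus_fold, drop_allgap_columns, fold

DEFAULT_WEIGHTS = (-4.0, 1.5, 3.0)  # (w0, w1 on -mean_z, w2 on sci)


@dataclass
class StructureScoreParams:
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    n_shuffles: int = 100
    min_loop: int = 3
    dinucleotide: bool = False
    threshold: float = 0.5
    max_z_rows: int | None = None  # cap rows entering the mean z (performance)


@dataclass
class StructureScore:
    window_id: str
    mean_z: float
    sci: float
    combined: float

    @property
    def high_confidence(self) -> bool:
        return self.combined > 0.5


def _mono_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson-style shuffle preserving dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for _ in range(50):  # retry until an Eulerian ordering is found
        trial = {a: list(bs) for a, bs in edges.items()}
        for bs in trial.values():
            rng.shuffle(bs)
        out = [seq[0]]
        cur = seq[0]
        ok = True
        for _step in range(len(seq) - 1):
            nxt_list = trial.get(cur)
            if not nxt_list:
                ok = False
                break
            cur = nxt_list.pop(0)
            out.append(cur)
        if ok:
            return "".join(out)
    return _mono_shuffle(seq, rng)


def mfe_zscore(
    sequence: str,
    n_shuffles: int = 100,
    seed: int | None = None,
    min_loop: int = 3,
    dinucleotide: bool = False,
) -> float:
    """(E_obs - mean E_shuffled) / sd(E_shuffled); 0 when sd is 0."""
    if n_shuffles < 30:
        raise ValueError("n_shuffles must be >= 30")
    rng = np.random.default_rng(seed)
    e_obs = fold(sequence, min_loop).energy
    shuffle = _dinucleotide_shuffle if dinucleotide else _mono_shuffle
    energies = np.array(
        [fold(shuffle(sequence, rng), min_loop).energy for _ in range(n_shuffles)]
    )
    sd = energies.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((e_obs - energies.mean()) / sd)


def sci(rows: list[str], min_loop: int = 3) -> float:
    """Structure conservation index: consensus energy over mean individual
    folding energy; 0 by convention when the mean individual energy is 0."""
    rows = drop_allgap_columns(rows)
    if len(rows) < 2:
        raise ValueError("sci needs at least 2 rows")
    individual = [fold(r.replace(GAP, ""), min_loop).energy for r in rows]
    mean_ind = float(np.mean(individual))
    if mean_ind == 0:
        return 0.0
    _st, cons_energy = consensus_fold(rows, min_loop)
    return float(cons_energy / mean_ind)


def combined_score(mean_z: float, sci_value: float,
                   weights: tuple[float, float, float] = DEFAULT_WEIGHTS) -> float:
    w0, w1, w2 = weights
    x = w0 + w1 * (-mean_z) + w2 * sci_value
    return 1.0 / (1.0 + math.exp(-x))


def structure_score(
    region_alignment: RegionAlignment,
    params: StructureScoreParams = StructureScoreParams(),
    seed: int | None = None,
    window_id: str = "",
) -> StructureScore:
    """Score one alignment window for conserved structure."""
    rows_all = [region_alignment.rows[sp] for sp in region_alignment.species]
    rows = [r for r in drop_allgap_columns(rows_all) if r] if rows_all else []
    ungapped = [r.replace(GAP, "").replace(".", "") for r in rows]
    # a row needs at least 5 informative bases to contribute
    usable = [
        (r, u)
        for r, u in zip(rows, ungapped)
        if sum(1 for c in u if c in "ACGUT") >= 5
    ]
    if len(usable) == 0:
        return StructureScore(window_id, 0.0, 0.0, 0.0)
    z_rows = usable
    if params.max_z_rows is not None:
        z_rows = usable[: params.max_z_rows]
    zs = []
    for k, (_r, u) in enumerate(z_rows):
        row_seed = None if seed is None else seed + 1000 * k
        zs.append(
            mfe_zscore(u, params.n_shuffles, row_seed, params.min_loop, params.dinucleotide)
        )
    mean_z = float(np.mean(zs))
    if len(usable) >= 2:
        sci_value = sci([r for r, _u in usable], params.min_loop)
    else:
        sci_value = 0.0
    return StructureScore(
        window_id, mean_z, sci_value, combined_score(mean_z, sci_value, params.weights)
    )


def calibrate_score_weights(
    features: np.ndarray,
    labels: np.ndarray,
    l2: float = 1e-3,
) -> tuple[float, float, float]:
    """Refit the logistic weights on labeled windows.

    ``features`` is (n, 2): columns are (-mean_z, sci); ``labels`` in {0, 1}.
    """
    X = np.column_stack([np.ones(len(features)), np.asarray(features, float)])
    y = np.asarray(labels, float)

    def loss(w):
        z = X @ w
        # log(1 + exp(-|z|)) + max(0, -yz) form for stability
        ll = np.logaddexp(0.0, z) - y * z
        return float(ll.sum() + l2 * np.dot(w, w))

    res = minimize(loss, x0=np.array(DEFAULT_WEIGHTS), method="BFGS")
    w = res.x
    return float(w[0]), float(w[1]), float(w[2])
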