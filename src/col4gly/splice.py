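"""Maximum-entropy splice-site scoring and the splice-disruption screen.

Exonic substitutions near exon/intron junctions can abolish splicing even
when they read as innocuous missense changes, so every variant within 3
bases of a splice site is scored against a maximum-entropy splice model
before it enters any genotype-phenotype stage.  A variant is flagged as
splice-affecting when its mutant window scores more than 15% lower than
the wild-type window, strictly.

The model here is the classic constrained maximum-entropy distribution
over splice windows: the distribution of maximal entropy whose
per-position and adjacent-pair nucleotide marginals match a training set
of true sites.  On this (chain-structured) constraint set the model is
fitted by iterative proportional scaling, with exact marginals computed by
forward-backward message passing, so the 23-mer acceptor window never
requires enumerating 4^23 sequences.  Scores are log-odds (base 2)
against a factorized background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chain_model import ChainArchitecture

__all__ = [
    "SpliceModel",
    "SpliceAssessment",
    "DONOR_WINDOW",
    "ACCEPTOR_WINDOW",
    "SPLICE_PROXIMITY_BASES",
    "DEFAULT_SPLICE_THRESHOLD",
    "near_splice_site",
    "score_site",
    "train_maxent",
    "assess_splice_effect",
    "save_model",
    "load_model",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_WINDOW = 9  # last 3 exonic + first 6 intronic bases
ACCEPTOR_WINDOW = 23  # last 20 intronic + first 3 exonic bases
SPLICE_PROXIMITY_BASES = 3
DEFAULT_SPLICE_THRESHOLD = 0.15

_WINDOW_BY_KIND = {"donor_5prime": DONOR_WINDOW, "acceptor_3prime": ACCEPTOR_WINDOW}


@dataclass
class SpliceModel:
    """Chain-factorized maximum-entropy splice model.

    ``pair_potentials[i]`` is a 4x4 table over bases at window positions
    (i, i+1); the model probability of a window is the normalized product
    of its pair potentials.  ``background`` holds per-position base
    probabilities (uniform unless trained otherwise).
    """

    site_kind: str
    window_length: int
    pair_potentials: list[np.ndarray]
    background: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_z: float = 0.0

    def __post_init__(self) -> None:
        if self.site_kind not in _WINDOW_BY_KIND:
            raise ValueError(f"unknown site kind {self.site_kind!r}")
        if len(self.pair_potentials) != self.window_length - 1:
            raise ValueError("need one pair potential per adjacent position pair")
        if self.background is None:
            self.background = np.full((self.window_length, 4), 0.25)
        self._normalize()

    def _normalize(self) -> None:
        """Compute log partition function by the forward recursion."""
        message = np.ones(4)
        log_z = 0.0
        for pot in self.pair_potentials:
            message = message @ pot
            scale = message.sum()
            log_z += np.log(scale)
            message /= scale
        # message now sums to 1; remaining mass already folded into log_z
        self.log_z = float(log_z)

    def _encode(self, window: str) -> np.ndarray:
        window = window.upper()
        if len(window) != self.window_length:
            raise ValueError(
                f"window length {len(window)} != model window {self.window_length}"
            )
        try:
            return np.array([_BASE_INDEX[b] for b in window])
        except KeyError as exc:
            raise ValueError(f"invalid base {exc.args[0]!r} in window {window!r}") from exc

    def maxent_probability(self, window: str) -> float:
        idx = self._encode(window)
        log_p = -self.log_z
        for i, pot in enumerate(self.pair_potentials):
            value = pot[idx[i], idx[i + 1]]
            if value <= 0.0:
                return 0.0
            log_p += np.log(value)
        return float(np.exp(log_p))

    def background_probability(self, window: str) -> float:
        idx = self._encode(window)
        return float(np.prod(self.background[np.arange(self.window_length), idx]))

    def pair_marginals(self) -> list[np.ndarray]:
        """Exact adjacent-pair marginals by forward-backward messages."""
        n_edges = self.window_length - 1
        forward = [np.ones(4)]
        for pot in self.pair_potentials[:-1]:
            msg = forward[-1] @ pot
            forward.append(msg / msg.sum())
        backward = [np.ones(4)]
        for pot in reversed(self.pair_potentials[1:]):
            msg = pot @ backward[-1]
            backward.append(msg / msg.sum())
        backward.reverse()
        out = []
        for i in range(n_edges):
            joint = forward[i][:, None] * self.pair_potentials[i] * backward[i][None, :]
            out.append(joint / joint.sum())
        return out

    def position_marginals(self) -> np.ndarray:
        pairs = self.pair_marginals()
        marg = np.empty((self.window_length, 4))
        marg[0] = pairs[0].sum(axis=1)
        for i, joint in enumerate(pairs):
            marg[i + 1] = joint.sum(axis=0)
        return marg


def _empirical_pair_marginals(windows: list[str], length: int) -> list[np.ndarray]:
    counts = [np.zeros((4, 4)) for _ in range(length - 1)]
    for window in windows:
        idx = [_BASE_INDEX[b] for b in window.upper()]
        for i in range(length - 1):
            counts[i][idx[i], idx[i + 1]] += 1.0
    return [c / len(windows) for c in counts]


def train_maxent(
    site_kind: str,
    training_windows: list[str],
    min_windows: int = 50,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> SpliceModel:
    """Fit the maximum-entropy splice model to aligned true-site windows.

    Iterative proportional scaling on the adjacent-pair marginals (which
    subsume the per-position marginals on a chain); converged when every
    model pair marginal is within ``tol`` of its empirical target.
    Contexts never seen in training keep probability zero, the
    maximum-likelihood limit.
    """
    if site_kind not in _WINDOW_BY_KIND:
        raise ValueError(f"unknown site kind {site_kind!r}")
    length = _WINDOW_BY_KIND[site_kind]
    if len(training_windows) < min_windows:
        raise ValueError(
            f"need at least {min_windows} training windows, got {len(training_windows)}"
        )
    lengths = {len(w) for w in training_windows}
    if lengths != {length}:
        raise ValueError(f"training windows must all have length {length}, saw {lengths}")
    for window in training_windows:
        if any(b not in _BASE_INDEX for b in window.upper()):
            raise ValueError(f"invalid base in training window {window!r}")

    targets = _empirical_pair_marginals(training_windows, length)
    model = SpliceModel(
        site_kind, length, [np.ones((4, 4)) for _ in range(length - 1)]
    )
    for _ in range(max_iter):
        current = model.pair_marginals()
        deviation = max(
            float(np.abs(cur - tgt).max()) for cur, tgt in zip(current, targets)
        )
        if deviation < tol:
            break
        for i, tgt in enumerate(targets):
            cur = model.pair_marginals()[i]
            ratio = np.divide(tgt, cur, out=np.zeros_like(tgt), where=cur > 0)
            model.pair_potentials[i] = model.pair_potentials[i] * ratio
            model._normalize()
    else:
        raise RuntimeError(
            f"iterative proportional scaling did not reach {tol} in {max_iter} iterations"
        )
    return model


def score_site(model: SpliceModel, window: str) -> float:
    """Log-odds score: log2 maxent probability over background probability."""
    p_model = model.maxent_probability(window)
    p_background = model.background_probability(window)
    if p_model <= 0.0:
        return float("-inf")
    return float(np.log2(p_model / p_background))


def near_splice_site(arch: ChainArchitecture, cdna_position: int) -> bool:
    """True iff the CDS position lies within 3 bases of an internal junction.

    Only exonic positions are in scope, so the qualifying positions are the
    3 terminal exonic bases on each side of each internal exon/exon join;
    the CDS start and the final exon end are not splice junctions.
    """
    if not arch.exon_map:
        return False
    cds_end = arch.exon_map[-1].cdna_end
    if not 1 <= cdna_position <= cds_end:
        raise IndexError(f"cDNA position {cdna_position} outside CDS (1..{cds_end})")
    for span in arch.exon_map[:-1]:  # donor side of each internal junction
        if span.cdna_end - (SPLICE_PROXIMITY_BASES - 1) <= cdna_position <= span.cdna_end:
            return True
    for span in arch.exon_map[1:]:  # acceptor side
        if span.cdna_start <= cdna_position <= span.cdna_start + (SPLICE_PROXIMITY_BASES - 1):
            return True
    return False


@dataclass(frozen=True)
class SpliceAssessment:
    wt_score: float
    mut_score: float
    relative_drop: float
    affected: bool


def assess_splice_effect(
    wt_score: float, mut_score: float, threshold: float = DEFAULT_SPLICE_THRESHOLD
) -> SpliceAssessment:
    """Flag a variant whose mutant score drops more than ``threshold``.

    The drop is measured relative to |wild-type score| so the rule stays
    directional when the wild-type score is negative; a drop of exactly the
    threshold does NOT flag the variant (the rule is strict).
    """
    if not (np.isfinite(wt_score) and np.isfinite(mut_score)):
        raise ValueError("scores must be finite")
    if wt_score != 0.0:
        relative_drop = (wt_score - mut_score) / abs(wt_score)
    else:
        relative_drop = float("inf") if mut_score < 0 else 0.0
    return SpliceAssessment(
        wt_score=float(wt_score),
        mut_score=float(mut_score),
        relative_drop=float(relative_drop),
        affected=bool(relative_drop > threshold),
    )


# ---------------------------------------------------------------------------
# parameter-table files: plain text, key-value

def save_model(model: SpliceModel, path: str | Path) -> None:
    lines = [
        f"site_kind\t{model.site_kind}",
        f"window_length\t{model.window_length}",
    ]
    for i, pot in enumerate(model.pair_potentials):
        for a, base_a in enumerate(BASES):
            for b, base_b in enumerate(BASES):
                lines.append(f"pair\t{i}\t{base_a}{base_b}\t{float(pot[a, b])!r}")
    for i in range(model.window_length):
        for a, base in enumerate(BASES):
            lines.append(f"background\t{i}\t{base}\t{float(model.background[i, a])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> SpliceModel:
    site_kind = None
    window_length = None
    pair_entries: dict[tuple[int, int, int], float] = {}
    background_entries: dict[tuple[int, int], float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "site_kind":
            site_kind = fields[1]
        elif fields[0] == "window_length":
            window_length = int(fields[1])
        elif fields[0] == "pair":
            i, duo, value = int(fields[1]), fields[2], float(fields[3])
            pair_entries[(i, _BASE_INDEX[duo[0]], _BASE_INDEX[duo[1]])] = value
        elif fields[0] == "background":
            i, base, value = int(fields[1]), fields[2], float(fields[3])
            background_entries[(i, _BASE_INDEX[base])] = value
    if site_kind is None or window_length is None:
        raise ValueError(f"incomplete splice model file {path}")
    pots = [np.ones((4, 4)) for _ in range(window_length - 1)]
    for (i, a, b), value in pair_entries.items():
        pots[i][a, b] = value
    background = np.full((window_length, 4), 0.25)
    for (i, a), value in background_entries.items():
        background[i, a] = value
    return SpliceModel(site_kind, window_length, pots, background)
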