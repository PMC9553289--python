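"""Experimental design, level calibration and mora-accuracy scoring.

The design crosses five band counts (2, 4, 8, 16, 20), three original
segment durations (20, 40, 80 ms) and three stretching ratios (1.0, 1.5,
2.0) -- 45 cells -- plus one unprocessed control, 46 conditions in all.
Each listener runs five blocks of all 46 conditions (230 trials) with a
distinct sentence per trial; sentence-condition pairings are cyclically
shifted between listeners.  Transcriptions are scored per mora (the
Japanese syllable-like timing unit) against the target by edit-distance
alignment; blanks are incorrect and homophones count as correct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .waveform import Waveform

BAND_COUNTS = (2, 4, 8, 16, 20)
SEGMENT_DURATIONS_MS = (20.0, 40.0, 80.0)
STRETCH_RATIOS = (1.0, 1.5, 2.0)

#: Kana pairs pronounced identically in modern Japanese (voiced ji/zu pairs
#: and particle readings); user maps extend or replace this.
DEFAULT_HOMOPHONES: tuple[tuple[str, str], ...] = (
    ("ぢ", "じ"),  # di/ji kana
    ("づ", "ず"),  # du/zu kana
    ("は", "わ"),  # topic particle ha read wa
    ("へ", "え"),  # directional particle he read e
    ("を", "お"),  # object particle wo read o
    ("du", "zu"),
    ("di", "ji"),
)


@dataclass(frozen=True)
class Condition:
    """One cell of the design (or the unprocessed control)."""

    n_bands: int | None
    segment_ms: float | None
    stretch_ratio: float | None
    control: bool = False

    def label(self) -> str:
        if self.control:
            return "original"
        return f"{self.n_bands}band_{self.segment_ms:g}ms_r{self.stretch_ratio:g}"


@dataclass(frozen=True)
class ConditionGrid:
    conditions: tuple[Condition, ...]

    def __len__(self) -> int:
        return len(self.conditions)


@dataclass(frozen=True)
class TrialPlan:
    """One listener's five randomized blocks of (condition, sentence)."""

    listener: int
    blocks: tuple[tuple[tuple[Condition, object], ...], ...]
    seed: int

    @property
    def trials(self) -> list[tuple[Condition, object]]:
        return [t for block in self.blocks for t in block]


@dataclass(frozen=True)
class ScoredResponse:
    n_correct: int
    n_total: int
    verdicts: tuple[bool, ...]  # per target mora

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_total:
            raise ValueError("0 <= n_correct <= n_total violated")

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total if self.n_total else 0.0


def condition_grid() -> ConditionGrid:
    """The full 46-condition design: 5 x 3 x 3 cells plus the control."""
    cells = [
        Condition(b, d, r)
        for b, d, r in itertools.product(
            BAND_COUNTS, SEGMENT_DURATIONS_MS, STRETCH_RATIOS
        )
    ]
    cells.append(Condition(None, None, None, control=True))
    return ConditionGrid(tuple(cells))


N_BLOCKS = 5


def make_trial_plan(listener_index: int, sentence_pool, seed: int = 0) -> TrialPlan:
    """Randomize five blocks and allot sentences with a cyclic shift.

    Block orders depend only on (seed, block), so all listeners share the
    condition sequence and differ purely in the sentence rotation by
    ``listener_index`` -- the ideal counterbalancing scheme.  Each of the
    first 230 pool sentences is used exactly once per listener.
    """
    grid = condition_grid()
    n_trials = N_BLOCKS * len(grid)
    pool = list(sentence_pool)
    if len(pool) < n_trials:
        raise ValueError(
            f"sentence pool has {len(pool)} entries; need at least {n_trials}"
        )
    pool = pool[:n_trials]
    blocks = []
    slot = 0
    for b in range(N_BLOCKS):
        rng = np.random.default_rng([seed, b])
        order = rng.permutation(len(grid))
        block = []
        for idx in order:
            sentence = pool[(slot + listener_index) % n_trials]
            block.append((grid.conditions[idx], sentence))
            slot += 1
        blocks.append(tuple(block))
    return TrialPlan(listener=listener_index, blocks=tuple(blocks), seed=seed)


def calibrate_rms(wave: Waveform, reference: Waveform) -> Waveform:
    """Scale a waveform so its RMS matches the reference's (pure scaling)."""
    ref_rms = reference.rms()
    wav_rms = wave.rms()
    if ref_rms <= 0:
        raise ValueError("reference waveform is silent")
    if wav_rms <= 0:
        raise ValueError("cannot calibrate a silent waveform")
    return wave.replace(wave.samples * (ref_rms / wav_rms))


def _canonical_map(equivalence) -> dict:
    """Union-find canonicalization of an equivalence relation given as
    pairs, a dict token -> token, or dict token -> iterable of tokens."""
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb, key=str)] = min(ra, rb, key=str)

    if equivalence is None:
        pairs = []
    elif isinstance(equivalence, dict):
        pairs = []
        for k, v in equivalence.items():
            if isinstance(v, (list, tuple, set)):
                pairs.extend((k, x) for x in v)
            else:
                pairs.append((k, v))
    else:
        pairs = list(equivalence)
    for a, b in pairs:
        union(a, b)
    return {x: find(x) for x in parent}


def score_morae(
    response, target, equivalence=DEFAULT_HOMOPHONES
) -> ScoredResponse:
    """Count correct morae via minimum-edit-distance alignment.

    Tokens equal under the (symmetrized, transitive) equivalence relation
    match at cost 0; substitutions, insertions and deletions cost 1.  Ties
    between equal-cost alignments prefer matches.  ``n_total`` is the
    target length; an empty response scores zero.
    """
    tgt = list(target)
    rsp = list(response)
    if not tgt:
        raise ValueError("target must be nonempty")
    canon = _canonical_map(equivalence)

    def match(a, b) -> bool:
        return a == b or canon.get(a, a) == canon.get(b, b)

    nr, nt = len(rsp), len(tgt)
    # DP over (cost, -matches), lexicographic
    INF = (10**9, 0)
    cost = np.empty((nr + 1, nt + 1), dtype=object)
    for i in range(nr + 1):
        cost[i, 0] = (i, 0)
    for j in range(nt + 1):
        cost[0, j] = (j, 0)
    for i in range(1, nr + 1):
        for j in range(1, nt + 1):
            c_del = (cost[i - 1, j][0] + 1, cost[i - 1, j][1])
            c_ins = (cost[i, j - 1][0] + 1, cost[i, j - 1][1])
            if match(rsp[i - 1], tgt[j - 1]):
                c_diag = (cost[i - 1, j - 1][0], cost[i - 1, j - 1][1] - 1)
            else:
                c_diag = (cost[i - 1, j - 1][0] + 1, cost[i - 1, j - 1][1])
            cost[i, j] = min(c_diag, c_del, c_ins)
    # traceback, preferring matched diagonals
    verdicts = [False] * nt
    i, j = nr, nt
    while i > 0 and j > 0:
        is_match = match(rsp[i - 1], tgt[j - 1])
        c_diag = (
            (cost[i - 1, j - 1][0], cost[i - 1, j - 1][1] - 1)
            if is_match
            else (cost[i - 1, j - 1][0] + 1, cost[i - 1, j - 1][1])
        )
        if cost[i, j] == c_diag:
            if is_match:
                verdicts[j - 1] = True
            i, j = i - 1, j - 1
        elif cost[i, j] == (cost[i - 1, j][0] + 1, cost[i - 1, j][1]):
            i -= 1
        else:
            j -= 1
    n_correct = sum(verdicts)
    return ScoredResponse(n_correct=n_correct, n_total=nt,
                          verdicts=tuple(verdicts))


def export_response_table(scored_trials) -> pd.DataFrame:
    """Long-format response table, one row per target mora.

    ``scored_trials`` is an iterable of dicts (or tuples) with keys
    listener, sentence, condition, scored.  Columns: listener, sentence,
    bands, segment_ms, ratio, mora_index, correct -- directly consumable
    by mixed-model software.
    """
    rows = []
    for trial in scored_trials:
        if isinstance(trial, dict):
            listener, sentence = trial["listener"], trial["sentence"]
            cond, scored = trial["condition"], trial["scored"]
        else:
            listener, sentence, cond, scored = trial
        for k, ok in enumerate(scored.verdicts):
            rows.append({
                "listener": listener,
                "sentence": sentence,
                "bands": cond.n_bands,
                "segment_ms": cond.segment_ms,
                "ratio": cond.stretch_ratio,
                "mora_index": k,
                "correct": int(ok),
            })
    return pd.DataFrame(
        rows,
        columns=["listener", "sentence", "bands", "segment_ms", "ratio",
                 "mora_index", "correct"],
    )
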