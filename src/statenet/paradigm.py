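"""Multifeatured statistical-learning stimulus paradigm.

Four parallel feature streams (pitch, timbre, shape, color; 11 symbols
each) are bound into audiovisual stimuli: pitch and shape form the
audiovisual stream (a fixed bijection), while each stimulus index also
carries a standard timbre (auditory stream) and a standard color (visual
stream).  Patterns are triplets of stimuli.  Four categories of six
patterns each are used: standard patterns respect all transitional
regularities; deviant patterns copy a standard pattern but replace, in the
third stimulus only, the violated feature(s) with the value carried by the
first stimulus of a different standard pattern — timbre for auditory
deviants, color for visual deviants, and shape plus pitch together for
audiovisual-incongruent patterns.

A presentation stream has a familiarisation phase of standard patterns
only, followed by runs in which the four categories are equally and
randomly interleaved (a seeded permutation of an exactly balanced
multiset).  A surprise two-alternative forced-choice (2AFC) test pairs
standard with deviant patterns, 12 pairs per deviant modality, with the
within-pair presentation order counterbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "PatternSet",
    "StimulusStream",
    "build_pattern_set",
    "generate_stream",
    "transition_probabilities",
    "deviant_vs_standard_transitions",
    "build_2afc_test",
]

FEATURES = ("shape", "color", "pitch", "timbre")
CATEGORIES = ("standard", "auditory_deviant", "visual_deviant", "audiovisual_incongruent")

PITCHES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "B")
TIMBRES = (
    "reflective_string",
    "pop_flute",
    "tenor_sax",
    "grand_piano",
    "fingerstyle_bass",
    "future_flute",
    "swirling_piano",
    "smokey_clav",
    "pop_organ",
    "hollywood_strings",
    "electric_tremolo",
)
COLORS = (
    "rgb(192,0,0)",
    "rgb(160,81,16)",
    "rgb(132,140,142)",
    "rgb(255,192,0)",
    "rgb(175,170,105)",
    "rgb(0,176,80)",
    "rgb(70,181,211)",
    "rgb(173,173,219)",
    "rgb(0,32,96)",
    "rgb(112,48,160)",
    "rgb(127,127,127)",
)
SHAPES = tuple(f"shape{i:02d}" for i in range(11))

STIM_DURATION_MS = 400.0
ISI_MS = 150.0


class Stimulus(NamedTuple):
    shape: str
    color: str
    pitch: str
    timbre: str


@dataclass(frozen=True)
class PatternSet:
    """Six triplet patterns per category plus the feature couplings."""

    alphabets: dict[str, tuple[str, ...]]
    # symbol carried by stimulus index 0..10 in each feature stream
    assignment: dict[str, tuple[str, ...]]
    # index triplets of the six standard patterns
    standard_indices: tuple[tuple[int, int, int], ...]
    patterns: dict[str, tuple[tuple[Stimulus, Stimulus, Stimulus], ...]]
    # for each deviant category and pattern: the donor standard pattern index
    donors: dict[str, tuple[int, ...]]
    seed: int

    def stimulus(self, index: int) -> Stimulus:
        """The standard (regularity-respecting) stimulus at a stream index."""
        return Stimulus(*(self.assignment[f][index] for f in FEATURES))


def build_pattern_set(seed: int = 0) -> PatternSet:
    """Construct the 4 x 6 pattern inventory under the coupling constraints.

    Symbol-to-index assignments and the six standard index triplets are
    seeded pseudo-random; only the transitional-probability structure
    matters downstream.  The six standard patterns start on six distinct
    stimulus indices, which guarantees every deviant pattern has a donor
    standard pattern carrying a different value of the violated feature.
    """
    rng = np.random.default_rng(seed)
    alphabets = {"shape": SHAPES, "color": COLORS, "pitch": PITCHES, "timbre": TIMBRES}
    # pitch<->shape ride together on the stimulus index (audiovisual coupling);
    # timbre and color get their own seeded bijections onto the index
    assignment = {
        "shape": SHAPES,
        "pitch": PITCHES,
        "timbre": tuple(rng.permutation(TIMBRES)),
        "color": tuple(rng.permutation(COLORS)),
    }
    firsts = rng.choice(11, size=6, replace=False)
    standard_indices = []
    for f in firsts:
        trip = [int(f)]
        while len(trip) < 3:
            nxt = int(rng.integers(11))
            if nxt != trip[-1]:
                trip.append(nxt)
        standard_indices.append(tuple(trip))
    standard_indices = tuple(standard_indices)

    def stim(idx: int) -> Stimulus:
        return Stimulus(*(assignment[f][idx] for f in FEATURES))

    standards = tuple(tuple(stim(i) for i in trip) for trip in standard_indices)

    violated = {
        "auditory_deviant": ("timbre",),
        "visual_deviant": ("color",),
        "audiovisual_incongruent": ("shape", "pitch"),
    }
    patterns: dict[str, tuple] = {"standard": standards}
    donors: dict[str, tuple[int, ...]] = {}
    for cat, feats in violated.items():
        out, dn = [], []
        for k, trip in enumerate(standard_indices):
            third = trip[2]
            candidates = [
                j
                for j in range(6)
                if j != k and all(assignment[f][standard_indices[j][0]] != assignment[f][third] for f in feats)
            ]
            donor = int(rng.choice(candidates))
            repl = {f: assignment[f][standard_indices[donor][0]] for f in feats}
            last = standards[k][2]._replace(**repl)
            out.append((standards[k][0], standards[k][1], last))
            dn.append(donor)
        patterns[cat] = tuple(out)
        donors[cat] = tuple(dn)

    return PatternSet(
        alphabets=alphabets,
        assignment=assignment,
        standard_indices=standard_indices,
        patterns=patterns,
        donors=donors,
        seed=seed,
    )


@dataclass(frozen=True)
class StimulusStream:
    """Ordered pattern presentations with phase/run structure and timing."""

    entries: pd.DataFrame  # columns: phase, run, category, pattern_index
    stim_duration_ms: float = STIM_DURATION_MS
    isi_ms: float = ISI_MS

    def __post_init__(self) -> None:
        p1 = self.entries[self.entries["phase"] == 1]
        if not (p1["category"] == "standard").all():
            raise ValueError("phase 1 must contain only standard patterns")

    def stimulus_sequence(self, ps: PatternSet) -> list[Stimulus]:
        seq: list[Stimulus] = []
        for _, row in self.entries.iterrows():
            seq.extend(ps.patterns[row["category"]][row["pattern_index"]])
        return seq

    def to_events(self, ps: PatternSet) -> pd.DataFrame:
        """Flat stimulus-level event table with onsets in ms."""
        rows = []
        onset = 0.0
        for slot, (_, row) in enumerate(self.entries.iterrows()):
            for si, stim in enumerate(ps.patterns[row["category"]][row["pattern_index"]]):
                rows.append(
                    {
                        "onset_ms": onset,
                        "slot": slot,
                        "pattern_id": f"{row['category']}/{row['pattern_index']}",
                        "category": row["category"],
                        "stimulus_index": si,
                        **stim._asdict(),
                    }
                )
                onset += self.stim_duration_ms + self.isi_ms
        return pd.DataFrame(rows)

    def write_events(self, path: str | Path, ps: PatternSet) -> None:
        self.to_events(ps).to_csv(path, sep="\t", index=False)


def generate_stream(
    ps: PatternSet,
    phase1_n: int = 70,
    runs: int = 3,
    patterns_per_run: int = 460,
    seed: int = 0,
) -> StimulusStream:
    """Familiarisation phase plus balanced, randomly interleaved runs.

    Phase 1 holds ``phase1_n`` standard patterns; each of the ``runs``
    phase-2 runs holds exactly ``patterns_per_run / 4`` patterns of every
    category, in a seeded random order.
    """
    if patterns_per_run % 4 != 0:
        raise ValueError("patterns_per_run must be divisible by 4 (one quarter per category)")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(phase1_n):
        rows.append({"phase": 1, "run": 0, "category": "standard", "pattern_index": int(rng.integers(6))})
    per_cat = patterns_per_run // 4
    for run in range(1, runs + 1):
        block = [(cat, int(rng.integers(6))) for cat in CATEGORIES for _ in range(per_cat)]
        order = rng.permutation(len(block))
        for k in order:
            cat, idx = block[k]
            rows.append({"phase": 2, "run": run, "category": cat, "pattern_index": idx})
    return StimulusStream(entries=pd.DataFrame(rows))


def transition_probabilities(stream: StimulusStream, ps: PatternSet, feature: str) -> pd.DataFrame:
    """Empirical P(next symbol | current symbol) for one feature stream.

    Computed over the flattened stimulus sequence of the whole stream.
    Rows with at least one observed successor sum to 1; unobserved rows
    are all zero.
    """
    if feature not in FEATURES:
        raise KeyError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    seq = [getattr(s, feature) for s in stream.stimulus_sequence(ps)]
    if len(seq) < 2:
        raise ValueError("stream too short to estimate transitions")
    symbols = list(ps.alphabets[feature])
    pos = {s: i for i, s in enumerate(symbols)}
    counts = np.zeros((len(symbols), len(symbols)))
    for a, b in zip(seq[:-1], seq[1:]):
        counts[pos[a], pos[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    probs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return pd.DataFrame(probs, index=symbols, columns=symbols)


def deviant_vs_standard_transitions(stream: StimulusStream, ps: PatternSet) -> dict[str, float]:
    """Mean empirical probability of deviant-defining vs standard transitions.

    For each deviant category the defining transition is (feature value of
    the second stimulus) -> (altered feature value of the third stimulus)
    in the violated feature stream; standard transitions are the
    within-pattern transitions of the standard patterns in that stream.
    """
    violated = {"auditory_deviant": "timbre", "visual_deviant": "color", "audiovisual_incongruent": "pitch"}
    dev_probs, std_probs = [], []
    for cat, feature in violated.items():
        tp = transition_probabilities(stream, ps, feature)
        for pat in ps.patterns[cat]:
            dev_probs.append(tp.loc[getattr(pat[1], feature), getattr(pat[2], feature)])
        for pat in ps.patterns["standard"]:
            for a, b in ((pat[0], pat[1]), (pat[1], pat[2])):
                std_probs.append(tp.loc[getattr(a, feature), getattr(b, feature)])
    return {"mean_deviant": float(np.mean(dev_probs)), "mean_standard": float(np.mean(std_probs))}


def build_2afc_test(ps: PatternSet, seed: int = 0) -> pd.DataFrame:
    """36 standard/deviant pattern pairs for the surprise 2AFC test.

    12 pairs per deviant modality (each of the six deviant patterns used
    twice, paired with its source standard pattern); within each modality
    six pairs present the standard first and six the deviant first, so the
    order is counterbalanced 18/18 overall.
    """
    rng = np.random.default_rng(seed)
    modality_of = {"auditory_deviant": "auditory", "visual_deviant": "visual", "audiovisual_incongruent": "audiovisual"}
    rows = []
    for cat, modality in modality_of.items():
        pattern_ids = rng.permutation(np.repeat(np.arange(6), 2))
        orders = rng.permutation(["standard_first"] * 6 + ["deviant_first"] * 6)
        for idx, order in zip(pattern_ids, orders):
            rows.append(
                {
                    "modality": modality,
                    "standard_index": int(idx),
                    "deviant_category": cat,
                    "deviant_index": int(idx),
                    "order": order,
                }
            )
    df = pd.DataFrame(rows)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)
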