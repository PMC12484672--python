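"""Trial-sequence generation for the implicit visual-learning task.

The task pairs an orientation cue (vertical or horizontal grating, 1 s) with
an outcome (one of six aversive looming/sweeping stimuli, or an omitted
gray-screen outcome, 2 s) after a 0.5 s inter-stimulus interval.  In the
*stable* environment the expected pairing (vertical -> aversive,
horizontal -> omitted) holds with probability 5/6 (83.4%); the *volatile*
environment cycles the expected-pairing probability through 1/6, 1/2 and 5/6
in consecutive 24-trial sub-blocks.  Three 72-trial stable blocks are
presented; the first is excluded from analysis (movement habituation), the
second and third form the early-stable (ES) and late-stable (LS) analysis
epochs, and the volatile 72 trials form the VL epoch.

Counts are realized exactly (probability x block length, rounded), so every
session sees identical contingency totals; randomness only permutes the
order within each block.  The per-trial contingency bit ``u`` (0 = expected
pairing, 1 = unexpected) over the analyzed trials is the input to the
hierarchical Gaussian filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "SessionDesign",
    "generate_session",
    "contingency_vector",
    "epoch_index",
    "AVERSIVE_TYPES",
    "ANALYSIS_EPOCHS",
]

AVERSIVE_TYPES = (
    "sweep-left",
    "sweep-right",
    "sweep-left-loom",
    "sweep-right-loom",
    "slow-loom",
    "fast-loom",
)

ANALYSIS_EPOCHS = ("ES", "LS", "VL")


class ConfigurationError(ValueError):
    """Raised when a task-design configuration cannot be realized exactly."""


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of one session of the implicit visual-learning task.

    Defaults reproduce the published design: three 72-trial stable blocks at
    an expected-contingency probability of 5/6, followed by a 72-trial
    volatile epoch of three 24-trial sub-blocks at probabilities
    (1/6, 1/2, 5/6).
    """

    stable_blocks: int = 3
    trials_per_block: int = 72
    volatile_block_len: int = 24
    volatile_probs: tuple[float, ...] = (1 / 6, 1 / 2, 5 / 6)
    stable_expected_prob: float = 5 / 6
    n_aversive_types: int = 6
    cue_duration_s: float = 1.0
    isi_s: float = 0.5
    outcome_duration_s: float = 2.0
    iti_s: float = 0.7
    #: one seed per stable block plus one for the volatile block
    seeds: tuple[int, ...] = (11, 12, 13, 14)
    exclude_first_stable_block: bool = True
    #: balance unexpected-contingency positions across cue types within a block
    balance_unexpected_across_cues: bool = True

    def __post_init__(self) -> None:
        if self.trials_per_block % (2 * self.n_aversive_types) != 0:
            raise ConfigurationError(
                "trials_per_block must be divisible by 2 * n_aversive_types "
                f"(got {self.trials_per_block} and {self.n_aversive_types})"
            )
        if len(self.volatile_probs) * self.volatile_block_len != self.trials_per_block:
            raise ConfigurationError(
                "len(volatile_probs) * volatile_block_len must equal trials_per_block"
            )
        n_blocks = self.stable_blocks + 1
        if len(self.seeds) != n_blocks:
            raise ConfigurationError(
                f"need one seed per block: {n_blocks} "
                f"({self.stable_blocks} stable + 1 volatile), got {len(self.seeds)}"
            )
        if len(set(self.seeds)) != len(self.seeds):
            warnings.warn("duplicate block seeds", stacklevel=2)

    @property
    def trial_duration_s(self) -> float:
        return self.cue_duration_s + self.isi_s + self.outcome_duration_s + self.iti_s

    def with_seeds(self, seeds: Sequence[int]) -> "DesignConfig":
        return replace(self, seeds=tuple(int(s) for s in seeds))


def _contingency_bit(cue: str, outcome: str) -> int:
    """0 for an expected pairing (vertical-aversive or horizontal-omitted)."""
    expected = (cue == "vertical") == (outcome == "aversive")
    return 0 if expected else 1


def _block_pairs(n: int, p_expected: float, rng: np.random.Generator,
                 balance_across_cues: bool) -> list[tuple[str, str]]:
    """Build and shuffle the (cue, outcome) multiset of one block.

    Cue and outcome counts are balanced at n/2 each; the number of
    expected-contingency trials is round(p * n), split evenly between the
    vertical-aversive and horizontal-omitted pairings.
    """
    if n % 2:
        raise ConfigurationError("block length must be even for balanced counts")
    e = round(p_expected * n)
    if balance_across_cues and e % 2:
        raise ConfigurationError(
            f"expected-contingency count {e} is odd; cannot balance across cue "
            "types (set balance_unexpected_across_cues=False or adjust counts)"
        )
    if e % 2:
        v_av = e // 2 + int(rng.integers(2))
    else:
        v_av = e // 2
    h_om = e - v_av
    v_om = n // 2 - v_av
    h_av = n // 2 - h_om
    if min(v_av, h_om, v_om, h_av) < 0:
        raise ConfigurationError(
            f"expected-contingency count {e} incompatible with balanced "
            f"cue/outcome counts in a block of {n}"
        )
    pairs = (
        [("vertical", "aversive")] * v_av
        + [("horizontal", "omitted")] * h_om
        + [("vertical", "omitted")] * v_om
        + [("horizontal", "aversive")] * h_av
    )
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


@dataclass
class SessionDesign:
    """An ordered trial table of one presented session.

    ``trials`` holds every presented trial (including the excluded first
    stable block); the :attr:`analyzed` view restricts to the ES/LS/VL
    analysis epochs and carries the 1-based analyzed trial index ``k``.
    """

    trials: pd.DataFrame
    config: DesignConfig = field(repr=False, default=None)

    @property
    def analyzed(self) -> pd.DataFrame:
        view = self.trials[self.trials["epoch"].isin(ANALYSIS_EPOCHS)]
        return view.reset_index(drop=True)

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed)

    def contingency_vector(self) -> np.ndarray:
        """Binary vector u over the analyzed trials (HGF input)."""
        return self.analyzed["u"].to_numpy(dtype=np.int8)

    def epoch_index(self, epoch: str) -> np.ndarray:
        """0-based positions of an analysis epoch within the analyzed view."""
        if epoch not in ANALYSIS_EPOCHS:
            raise ValueError(f"unknown epoch {epoch!r}; expected one of {ANALYSIS_EPOCHS}")
        return np.flatnonzero((self.analyzed["epoch"] == epoch).to_numpy())

    def aversive_index(self) -> np.ndarray:
        """0-based positions of aversive-outcome trials in the analyzed view."""
        return np.flatnonzero((self.analyzed["outcome"] == "aversive").to_numpy())

    @property
    def timing(self) -> dict:
        """Stimulus timing in seconds, from the config or the trial table.

        A table loaded from CSV carries onsets but not the configuration;
        the cue/outcome durations then fall back to the task defaults while
        the trial spacing is read off the onsets.
        """
        if self.config is not None:
            return {
                "trial_duration_s": self.config.trial_duration_s,
                "cue_duration_s": self.config.cue_duration_s,
                "outcome_duration_s": self.config.outcome_duration_s,
            }
        onsets = self.trials["onset_s"].to_numpy()
        spacing = float(np.median(np.diff(onsets))) if len(onsets) > 1 else 4.2
        return {"trial_duration_s": spacing, "cue_duration_s": 1.0,
                "outcome_duration_s": 2.0}

    def validate(self) -> None:
        df = self.trials
        recomputed = [
            _contingency_bit(c, o) for c, o in zip(df["cue"], df["outcome"])
        ]
        if not np.array_equal(recomputed, df["u"].to_numpy()):
            raise AssertionError("stored contingency bits inconsistent with (cue, outcome)")
        if ((df["aversive_type"] == "none") != (df["outcome"] == "omitted")).any():
            raise AssertionError("aversive_type must be 'none' iff outcome omitted")

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: DesignConfig | None = None) -> "SessionDesign":
        return cls(pd.read_csv(path), config=config)


def generate_session(config: DesignConfig | None = None) -> SessionDesign:
    """Generate the full presented trial sequence of one session.

    Each block's order is a seeded permutation of a fixed label multiset, so
    identical configurations yield bit-identical sequences and every session
    sees the same contingency totals.
    """
    config = config or DesignConfig()
    n = config.trials_per_block
    blocks: list[pd.DataFrame] = []

    # stable blocks
    for b in range(config.stable_blocks):
        rng = np.random.default_rng(config.seeds[b])
        pairs = _block_pairs(
            n, config.stable_expected_prob, rng, config.balance_unexpected_across_cues
        )
        if b == config.stable_blocks - 2:
            epoch = "ES"
        elif b == config.stable_blocks - 1:
            epoch = "LS"
        else:
            epoch = "excluded" if config.exclude_first_stable_block else f"S{b + 1}"
        blocks.append(_assemble_block(pairs, block=b + 1, epoch=epoch, rng=rng,
                                      n_types=config.n_aversive_types))

    # volatile block: sub-blocks at the configured probabilities
    vol_seed = config.seeds[config.stable_blocks]
    sub_seqs = np.random.SeedSequence(vol_seed).spawn(len(config.volatile_probs) + 1)
    vol_pairs: list[tuple[str, str]] = []
    for p, ss in zip(config.volatile_probs, sub_seqs[:-1]):
        rng = np.random.default_rng(ss)
        vol_pairs.extend(
            _block_pairs(config.volatile_block_len, p, rng,
                         config.balance_unexpected_across_cues)
        )
    blocks.append(_assemble_block(vol_pairs, block=config.stable_blocks + 1,
                                  epoch="VL", rng=np.random.default_rng(sub_seqs[-1]),
                                  n_types=config.n_aversive_types))

    trials = pd.concat(blocks, ignore_index=True)
    trials.index += 1
    trials.insert(0, "k_presented", trials.index)

    # analyzed 1-based index k; 0 marks non-analyzed trials
    analyzed = trials["epoch"].isin(ANALYSIS_EPOCHS).to_numpy()
    k = np.zeros(len(trials), dtype=int)
    k[analyzed] = np.arange(1, analyzed.sum() + 1)
    trials.insert(1, "k", k)

    # stimulus timing
    dt = config.trial_duration_s
    onset = (trials["k_presented"].to_numpy() - 1) * dt
    trials["onset_s"] = onset
    trials["outcome_onset_s"] = onset + config.cue_duration_s + config.isi_s

    session = SessionDesign(trials.reset_index(drop=True), config=config)
    session.validate()
    return session


def _assemble_block(pairs: list[tuple[str, str]], block: int, epoch: str,
                    rng: np.random.Generator, n_types: int) -> pd.DataFrame:
    """Attach contingency bits and a balanced aversive-subtype assignment."""
    cues, outcomes = zip(*pairs)
    u = [_contingency_bit(c, o) for c, o in pairs]
    av_slots = [i for i, o in enumerate(outcomes) if o == "aversive"]
    if len(av_slots) % n_types:
        raise ConfigurationError(
            f"{len(av_slots)} aversive trials not divisible by {n_types} subtypes"
        )
    per_type = len(av_slots) // n_types
    multiset = np.repeat(np.arange(n_types), per_type)
    assignment = multiset[rng.permutation(len(multiset))]
    types = ["none"] * len(pairs)
    for slot, t in zip(av_slots, assignment):
        types[slot] = AVERSIVE_TYPES[t % len(AVERSIVE_TYPES)] if n_types <= len(
            AVERSIVE_TYPES) else f"type-{t}"
    return pd.DataFrame(
        {
            "block": block,
            "epoch": epoch,
            "cue": cues,
            "outcome": outcomes,
            "aversive_type": types,
            "u": u,
        }
    )


# ---------------------------------------------------------------------------
# thin functional wrappers (module-level operation surface)

def contingency_vector(session: SessionDesign) -> np.ndarray:
    """Binary contingency vector over the analyzed trials."""
    return session.contingency_vector()


def epoch_index(session: SessionDesign, epoch: str) -> np.ndarray:
    """Positions of one analysis epoch within the analyzed view."""
    return session.epoch_index(epoch)
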