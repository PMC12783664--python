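"""Learning and evaluation protocol simulation with synthetic agents.

The training protocol pairs each soundscape with its image: within a glyph
group, the rotation variants are presented forward then in reverse (e.g.
E0, E90, E180, E270, E270, E180, E90, E0), the whole sequence repeated
three times, followed by two forced-choice probe questions (up to three
attempts each, feedback at the end).  Six of the twelve groups are learned
— always including the dot, two-dot and line groups, which open the
session — and the full plan is traversed twice.

Evaluation presents every stimulus (learned and novel alike) twice in
random order as a five-alternative forced choice: the correct image plus
two familiar-stimulus and two novel-stimulus distractors, no feedback.
Guessing uniformly over the five options succeeds 20% of the time; an
agent that first classifies the heard soundscape as familiar or novel and
guesses within that category faces 3 same-category options out of 5, so
its chance level rises to 1/3.

Agents are pluggable: a uniform random guesser, the familiarity-gated
guesser, and an ideal acoustic template matcher that compares magnitude
spectrograms of the heard soundscape against renderings of each candidate
image under its trained mapping (optionally a different mapping than the
one that produced the audio — the mismapped observer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sonify import MappingSpec, Soundscape, sonify, sonify_control
from .stimuli import FamiliarityPartition, StimulusSet

__all__ = [
    "LearningBlock",
    "LearningPlan",
    "EvalTrial",
    "SessionResult",
    "build_learning_plan",
    "build_evaluation",
    "run_session",
    "chance_level",
    "above_chance_test",
    "Agent",
    "RandomGuesser",
    "FamiliarityGated",
    "TemplateObserver",
    "random_guesser",
    "familiarity_gated",
    "template_observer",
    "mismapped_observer",
    "make_provider",
    "make_control_provider",
]


# ---------------------------------------------------------------------------
# plans and trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LearningBlock:
    """One group's pass through the learning session."""

    group_id: str
    presentation_sequence: tuple[str, ...]   # forward-then-reverse, repeated
    probe_ids: tuple[str, ...]               # soundscapes probed after the block
    options: tuple[str, ...]                 # learned variants shown as choices


@dataclass(frozen=True)
class LearningPlan:
    blocks: tuple[LearningBlock, ...]
    group_order: tuple[str, ...]
    traversals: int
    repetitions: int
    max_attempts: int
    seed: int


@dataclass(frozen=True)
class EvalTrial:
    """One 5-alternative forced-choice trial."""

    heard_id: str
    option_ids: tuple[str, ...]
    is_heard_familiar: bool

    def __post_init__(self):
        if len(self.option_ids) != len(set(self.option_ids)):
            raise ValueError("trial options must be distinct")
        if self.heard_id not in self.option_ids:
            raise ValueError("options must contain the heard stimulus")


def build_learning_plan(
    stimulus_set: StimulusSet,
    partition: FamiliarityPartition,
    seed: int,
    *,
    repetitions: int = 3,
    probes_per_block: int = 2,
    max_attempts: int = 3,
    traversals: int = 2,
) -> LearningPlan:
    """Deterministic learning plan for the familiar groups.

    Group order puts the forced first groups (dot, two-dot, line) ahead in
    their canonical order; the remaining familiar groups follow in seeded
    random order.  The whole ordered plan is traversed ``traversals``
    times; probe soundscapes are drawn per block without replacement from
    that group's variants (with replacement only when the group has fewer
    variants than probes, as for the single dot).
    """
    rng = np.random.default_rng(seed)
    familiar = list(partition.familiar_groups)
    forced = [g for g in ("DOT", "PP", "D") if g in familiar]
    rest = [g for g in familiar if g not in forced]
    order = forced + [rest[i] for i in rng.permutation(len(rest))]

    blocks = []
    for _ in range(traversals):
        for gid in order:
            variants = tuple(stimulus_set.ids_in_group(gid))
            forward = list(variants)
            one_pass = tuple(forward + forward[::-1]) * repetitions
            replace = len(variants) < probes_per_block
            probe_idx = rng.choice(len(variants), size=probes_per_block, replace=replace)
            blocks.append(
                LearningBlock(
                    group_id=gid,
                    presentation_sequence=one_pass,
                    probe_ids=tuple(variants[i] for i in probe_idx),
                    options=variants,
                )
            )
    return LearningPlan(
        blocks=tuple(blocks),
        group_order=tuple(order),
        traversals=traversals,
        repetitions=repetitions,
        max_attempts=max_attempts,
        seed=seed,
    )


def build_evaluation(
    stimulus_set: StimulusSet,
    partition: FamiliarityPartition,
    seed: int,
    *,
    presentations: int = 2,
    n_familiar_distractors: int = 2,
    n_novel_distractors: int = 2,
) -> list[EvalTrial]:
    """Evaluation trial list: every stimulus heard ``presentations`` times.

    Each trial offers the correct image plus two familiar-stimulus and two
    novel-stimulus distractors (heard excluded from the distractor pools),
    in seeded random option order; trial order is fully randomised.
    """
    familiar = list(partition.familiar_ids)
    novel = list(partition.novel_ids)
    if len(familiar) < n_familiar_distractors + 1 or len(novel) < n_novel_distractors + 1:
        raise ValueError(
            "familiar and novel pools must each exceed the distractor count"
        )
    rng = np.random.default_rng(seed)
    heard_seq = [sid for sid in stimulus_set.ids for _ in range(presentations)]
    heard_seq = [heard_seq[i] for i in rng.permutation(len(heard_seq))]

    trials = []
    for heard in heard_seq:
        is_fam = partition.is_familiar(heard)
        fam_pool = [s for s in familiar if s != heard]
        nov_pool = [s for s in novel if s != heard]
        fam_d = [fam_pool[i] for i in rng.choice(len(fam_pool), n_familiar_distractors, replace=False)]
        nov_d = [nov_pool[i] for i in rng.choice(len(nov_pool), n_novel_distractors, replace=False)]
        options = [heard] + fam_d + nov_d
        options = [options[i] for i in rng.permutation(len(options))]
        trials.append(EvalTrial(heard_id=heard, option_ids=tuple(options), is_heard_familiar=is_fam))
    return trials


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

class Agent:
    """Behavioural contract: choose one option id per probe or trial."""

    #: set True when the agent needs the heard waveform (templates etc.)
    needs_audio = False

    def respond(self, heard_id: str, options, heard_sound: Soundscape | None = None) -> str:
        raise NotImplementedError

    def update(self, heard_id: str, correct_id: str) -> None:
        """Feedback hook called after a learning probe resolves."""


class RandomGuesser(Agent):
    """Uniform guess over the displayed options."""

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def respond(self, heard_id, options, heard_sound=None):
        return options[self.rng.integers(len(options))]


class FamiliarityGated(Agent):
    """Classify the heard soundscape as familiar vs novel, then guess
    uniformly among the options of that category.

    With perfect classification (``miss_rate=0``) this is the idealised
    upper bound of the familiarity strategy; ``miss_rate`` flips the
    classification with the given probability for sensitivity analyses.
    """

    def __init__(self, partition: FamiliarityPartition, seed: int = 0, miss_rate: float = 0.0):
        self.partition = partition
        self.rng = np.random.default_rng(seed)
        self.miss_rate = miss_rate

    def respond(self, heard_id, options, heard_sound=None):
        heard_fam = self.partition.is_familiar(heard_id)
        if self.miss_rate > 0 and self.rng.random() < self.miss_rate:
            heard_fam = not heard_fam
        gated = [o for o in options if self.partition.is_familiar(o) == heard_fam]
        pool = gated if gated else list(options)
        return pool[self.rng.integers(len(pool))]


class TemplateObserver(Agent):
    """Ideal acoustic matcher: pick the option whose rendered soundscape
    best matches the heard one.

    Candidate images are rendered under the observer's trained mapping and
    compared by normalised cross-correlation of magnitude spectrograms
    (frame = one time step, no overlap).  With a matched mapping this is an
    ideal observer: every stimulus is its own unique best match.
    """

    needs_audio = True

    def __init__(self, stimulus_set: StimulusSet, spec: MappingSpec, *, nfft: int = 1024):
        self.stimulus_set = stimulus_set
        self.spec = spec
        self.nfft = nfft
        self._templates: dict[str, np.ndarray] = {}

    def _spectrogram(self, s: Soundscape) -> np.ndarray:
        son = np.asarray(s.sonification_samples)
        bounds = self.spec.step_boundaries()
        frames = [son[bounds[c] : bounds[c + 1]] for c in range(self.spec.n_steps)]
        return np.stack([np.abs(np.fft.rfft(f, n=self.nfft)) for f in frames])

    def _template(self, sid: str) -> np.ndarray:
        if sid not in self._templates:
            img = self.stimulus_set.image(sid)
            self._templates[sid] = self._spectrogram(sonify(img, self.spec))
        return self._templates[sid]

    def respond(self, heard_id, options, heard_sound=None):
        if heard_sound is None:
            raise ValueError("template observer needs the heard soundscape")
        heard = self._spectrogram(heard_sound).ravel()
        hn = np.linalg.norm(heard)
        best, best_score = options[0], -np.inf
        for o in options:
            tmpl = self._template(o).ravel()
            denom = hn * np.linalg.norm(tmpl)
            score = float(heard @ tmpl / denom) if denom > 0 else 0.0
            if score > best_score:
                best, best_score = o, score
        return best


def random_guesser(seed: int = 0) -> RandomGuesser:
    return RandomGuesser(seed)


def familiarity_gated(partition: FamiliarityPartition, seed: int = 0, miss_rate: float = 0.0) -> FamiliarityGated:
    return FamiliarityGated(partition, seed, miss_rate)


def template_observer(stimulus_set: StimulusSet, spec: MappingSpec) -> TemplateObserver:
    return TemplateObserver(stimulus_set, spec)


def mismapped_observer(
    stimulus_set: StimulusSet, train_spec: MappingSpec, test_spec: MappingSpec
):
    """Template observer trained under one mapping, heard audio rendered
    under another.  Returns ``(agent, provider)``: pass both to
    :func:`run_session`."""
    return TemplateObserver(stimulus_set, train_spec), make_provider(stimulus_set, test_spec)


def make_provider(stimulus_set: StimulusSet, spec: MappingSpec):
    """Caching stimulus_id -> Soundscape renderer for a structured mapping."""
    cache: dict[str, Soundscape] = {}

    def provider(sid: str) -> Soundscape:
        if sid not in cache:
            cache[sid] = sonify(stimulus_set.image(sid), spec, source_id=sid)
        return cache[sid]

    return provider


def make_control_provider(tone_map, spec: MappingSpec):
    """stimulus_id -> Soundscape renderer for the single-tone control scheme."""
    cache: dict[str, Soundscape] = {}

    def provider(sid: str) -> Soundscape:
        if sid not in cache:
            cache[sid] = sonify_control(sid, tone_map, spec)
        return cache[sid]

    return provider


# ---------------------------------------------------------------------------
# session execution and analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionResult:
    """Per-trial records plus aggregate accuracies (percent)."""

    trials: pd.DataFrame
    mode: str
    partition: FamiliarityPartition | None = field(default=None, repr=False)

    @property
    def accuracy(self) -> float:
        """Percent correct (attempt 1 in learning mode)."""
        return 100.0 * self.trials["correct"].mean()

    @property
    def attempt1_accuracy(self) -> float:
        return self.accuracy

    @property
    def accuracy_familiar(self) -> float:
        sub = self.trials[self.trials["is_heard_familiar"] == True]  # noqa: E712
        return 100.0 * sub["correct"].mean() if len(sub) else float("nan")

    @property
    def accuracy_novel(self) -> float:
        sub = self.trials[self.trials["is_heard_familiar"] == False]  # noqa: E712
        return 100.0 * sub["correct"].mean() if len(sub) else float("nan")

    def summary(self) -> pd.Series:
        out = {"mode": self.mode, "n_trials": len(self.trials), "accuracy_pct": self.accuracy}
        if self.mode == "evaluation":
            out["accuracy_familiar_pct"] = self.accuracy_familiar
            out["accuracy_novel_pct"] = self.accuracy_novel
        return pd.Series(out)


def _check_choice(choice, options):
    if choice not in options:
        raise RuntimeError(
            f"protocol violation: agent chose {choice!r}, not among options {options}"
        )


def run_session(agent: Agent, task, provider=None, seed: int = 0) -> SessionResult:
    """Run an agent through a learning plan or an evaluation trial list.

    Learning mode (``task`` is a :class:`LearningPlan`): each probe allows
    up to ``max_attempts`` responses; after a wrong attempt the chosen
    option is removed from the candidate set, and feedback (the correct
    pairing) is delivered once the probe resolves.  Only attempt-1
    correctness enters the accuracy.  Evaluation mode (``task`` is a list
    of :class:`EvalTrial`): one response per trial, no feedback.
    """
    if isinstance(task, LearningPlan):
        return _run_learning(agent, task, provider)
    return _run_evaluation(agent, list(task), provider)


def _hear(agent, provider, sid):
    if agent.needs_audio:
        if provider is None:
            raise ValueError("this agent needs a soundscape provider")
        return provider(sid)
    return None


def _run_learning(agent: Agent, plan: LearningPlan, provider) -> SessionResult:
    rows = []
    idx = 0
    for block in plan.blocks:
        for heard in block.probe_ids:
            remaining = list(block.options)
            sound = _hear(agent, provider, heard)
            first_choice = None
            solved = False
            attempts = 0
            for attempt in range(1, plan.max_attempts + 1):
                choice = agent.respond(heard, tuple(remaining), sound)
                _check_choice(choice, remaining)
                attempts = attempt
                if attempt == 1:
                    first_choice = choice
                if choice == heard:
                    solved = True
                    break
                remaining.remove(choice)
                if not remaining:
                    break
            agent.update(heard, heard)  # feedback: correct pairing replayed
            rows.append(
                {
                    "trial_index": idx,
                    "phase": "learning",
                    "group_id": block.group_id,
                    "heard_id": heard,
                    "options": "|".join(block.options),
                    "choice": first_choice,
                    "correct": first_choice == heard,
                    "attempts_used": attempts,
                    "solved": solved,
                    "is_heard_familiar": True,
                }
            )
            idx += 1
    return SessionResult(trials=pd.DataFrame(rows), mode="learning")


def _run_evaluation(agent: Agent, trials: list[EvalTrial], provider) -> SessionResult:
    rows = []
    for i, trial in enumerate(trials):
        sound = _hear(agent, provider, trial.heard_id)
        choice = agent.respond(trial.heard_id, trial.option_ids, sound)
        _check_choice(choice, trial.option_ids)
        rows.append(
            {
                "trial_index": i,
                "phase": "evaluation",
                "heard_id": trial.heard_id,
                "options": "|".join(trial.option_ids),
                "choice": choice,
                "correct": choice == trial.heard_id,
                "is_heard_familiar": trial.is_heard_familiar,
            }
        )
    return SessionResult(trials=pd.DataFrame(rows), mode="evaluation")


# ---------------------------------------------------------------------------
# analytic chance levels and exact binomial test
# ---------------------------------------------------------------------------

def chance_level(option_counts, heard_category: str | None = None) -> float:
    """Analytic guess probability for a forced choice.

    ``option_counts`` maps category labels to option counts.  With no
    ``heard_category`` the guess is uniform over all options (1/total,
    e.g. 1/5 = 20% for the evaluation trials); with a category it is
    uniform over that category's options (3 same-category options of 5
    gives 1/3).
    """
    total = sum(option_counts.values())
    if total <= 0:
        raise ValueError("no options")
    if heard_category is None:
        return 1.0 / total
    n = option_counts.get(heard_category, 0)
    if n <= 0:
        raise ValueError(f"no options in category {heard_category!r}")
    return 1.0 / n


def above_chance_test(correct: int, total: int, p0: float) -> float:
    """Exact binomial tail probability of >= ``correct`` successes under p0."""
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie strictly between 0 and 1")
    if total <= 0 or not (0 <= correct <= total):
        raise ValueError("need 0 <= correct <= total with total > 0")
    return float(stats.binomtest(correct, total, p0, alternative="greater").pvalue)
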