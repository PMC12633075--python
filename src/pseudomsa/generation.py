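"""Fragment sampling, two-stage generation and candidate ranking.

A pseudoMSA block explores the sequence space around a query's fold by
iterating over a coverage schedule and a Cartesian grid of decoding
hyperparameters.  For each (coverage, grid point) setting a contiguous
fragment is drawn uniformly, abstracted into up to N structural (3Di)
hypotheses by stochastic beam search, and each hypothesis is back-
translated into up to M amino-acid fragments by multinomial sampling —
at most N*M rows per setting.  Candidates are ranked by length-normalized
log-likelihood so longer hypotheses are not unfairly penalized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alphabets import AminoSequence
from .backend import ConfigError, DecodingConfig, ScoredCandidate, TranslatorBackend

__all__ = [
    "CoverageSchedule",
    "FragmentSpec",
    "HyperparameterGrid",
    "GenerationRun",
    "GeneratedRow",
    "sample_fragment",
    "fragment_length",
    "length_normalized_score",
    "rank_hypotheses",
    "run_generation_block",
    "DEFAULT_ROW_BUDGET",
    "SHALLOW_ROW_BUDGET",
]

#: Pre-filter row budgets of the two generation protocols; the shallow
#: protocol halves the sequence count without hurting downstream accuracy.
DEFAULT_ROW_BUDGET = 450
SHALLOW_ROW_BUDGET = DEFAULT_ROW_BUDGET // 2


@dataclass(frozen=True)
class CoverageSchedule:
    """Fragment coverage fractions c in (0, 1]; defaults span 40-100%."""

    fractions: Tuple[float, ...] = (0.4, 0.6, 0.8, 1.0)

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ConfigError("coverage schedule must be non-empty")
        for c in self.fractions:
            if not (0 < c <= 1):
                raise ConfigError(f"coverage fraction {c} outside (0, 1]")


@dataclass(frozen=True)
class FragmentSpec:
    """A contiguous query window: 0-based start, half-open [start, start+length)."""

    start: int
    length: int
    coverage: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConfigError("fragment length must be >= 1")
        if self.start < 0:
            raise ConfigError("fragment start must be >= 0")


@dataclass(frozen=True)
class HyperparameterGrid:
    """Cartesian decoding grid: temperatures x top_k values x top_p values.

    ``None`` entries in ``top_ks``/``top_ps`` mean the control is unset at
    that grid point.
    """

    temperatures: Tuple[float, ...] = (0.9, 1.0, 1.1)
    top_ks: Tuple[Optional[int], ...] = (None, 40)
    top_ps: Tuple[Optional[float], ...] = (0.9, 0.95)

    def __post_init__(self) -> None:
        if not (self.temperatures and self.top_ks and self.top_ps):
            raise ConfigError("grid lists must be non-empty")

    def points(self) -> List[Tuple[float, Optional[int], Optional[float]]]:
        return [
            (t, k, p)
            for t in self.temperatures
            for k in self.top_ks
            for p in self.top_ps
        ]

    def __len__(self) -> int:
        return len(self.temperatures) * len(self.top_ks) * len(self.top_ps)


@dataclass(frozen=True)
class GenerationRun:
    """Configuration of one generation protocol run."""

    protocol: str = "default"
    seed: int = 0
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    schedule: CoverageSchedule = field(default_factory=CoverageSchedule)
    n_structures: int = 4  # N: structural hypotheses per fragment
    multiplier: int = 3  # M: back-translations per hypothesis
    alpha: float = 1.0  # length-penalty exponent for beam ranking
    target_row_count: Optional[int] = None
    n_repeats: int = 1  # independent seed-offset repetitions

    def __post_init__(self) -> None:
        if self.protocol not in ("default", "shallow"):
            raise ConfigError("protocol must be 'default' or 'shallow'")
        if self.n_structures < 1 or self.multiplier < 1 or self.n_repeats < 1:
            raise ConfigError("N, M and n_repeats must be >= 1")
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")

    @property
    def row_budget(self) -> int:
        """Pre-filter row cap; the shallow protocol targets half the default."""
        if self.target_row_count is not None:
            base = self.target_row_count
        else:
            base = DEFAULT_ROW_BUDGET
        return base // 2 if self.protocol == "shallow" else base


@dataclass(frozen=True)
class GeneratedRow:
    """One generated amino-acid fragment with full provenance."""

    sequence: str
    fragment: FragmentSpec
    grid_point: Tuple[float, Optional[int], Optional[float]]
    forward_rank: int
    backward_index: int
    repeat: int
    forward_score: float  # length-normalized log-likelihood of the 3Di hypothesis
    backward_logprob: float


def fragment_length(coverage: float, query_length: int) -> int:
    """Rounding rule for l = [c*L]: round-half-up, never below 1."""
    return max(1, int(np.floor(coverage * query_length + 0.5)))


def sample_fragment(
    query: AminoSequence, coverage: float, rng: np.random.Generator
) -> FragmentSpec:
    """Draw a fragment of length l = round(c*L) starting uniformly on [0, L-l]."""
    L = len(query)
    if L < 2:
        raise ConfigError("query must have length >= 2")
    if not (0 < coverage <= 1):
        raise ConfigError(f"coverage {coverage} outside (0, 1]")
    l = fragment_length(coverage, L)
    if l > L:
        l = L
    start = int(rng.integers(0, L - l + 1))
    return FragmentSpec(start=start, length=l, coverage=coverage)


def length_normalized_score(candidate: ScoredCandidate, alpha: float) -> float:
    """Cumulative log-likelihood divided by length**alpha.

    alpha=0 reduces to the raw cumulative log-probability; alpha=1 is full
    normalization, under which equal-per-token-rate sequences tie
    regardless of length.
    """
    if alpha < 0:
        raise ConfigError("alpha must be >= 0")
    n = len(candidate)
    if n < 1:
        raise ConfigError("candidate must have at least one token")
    return candidate.cumulative_logprob / (n ** alpha)


def rank_hypotheses(
    candidates: Sequence[ScoredCandidate], alpha: float
) -> List[ScoredCandidate]:
    """Stable descending sort by length-normalized score (permutation of input)."""
    if not candidates:
        raise ConfigError("cannot rank an empty candidate list")
    return sorted(
        candidates, key=lambda c: -length_normalized_score(c, alpha)
    )


def extract_fragment(query: AminoSequence, spec: FragmentSpec) -> AminoSequence:
    """Slice the query window named by ``spec``."""
    if spec.start + spec.length > len(query):
        raise ConfigError("fragment exceeds query bounds")
    return AminoSequence(
        query.residues[spec.start : spec.start + spec.length],
        id=f"{query.id}|frag{spec.start}+{spec.length}",
    )


def run_generation_block(
    query: AminoSequence,
    run: GenerationRun,
    backend: TranslatorBackend,
    rng: Optional[np.random.Generator] = None,
) -> List[GeneratedRow]:
    """Execute one full generation block over schedule x grid.

    Iterates every (coverage, temperature, top_k, top_p) setting across
    ``run.n_repeats`` seed-offset repetitions; each setting contributes at
    most N*M rows.  The total is capped at ``run.row_budget`` by trimming
    the lowest-ranked rows of the last settings.  Deterministic under a
    fixed (query, run, backend seed).
    """
    if rng is None:
        rng = np.random.default_rng(run.seed)
    rows: List[GeneratedRow] = []
    errors: List[str] = []
    budget = run.row_budget
    for repeat in range(run.n_repeats):
        for coverage in run.schedule.fractions:
            for gi, (temp, top_k, top_p) in enumerate(run.grid.points()):
                if len(rows) >= budget:
                    break
                spec = sample_fragment(query, coverage, rng)
                fragment = extract_fragment(query, spec)
                cfg = DecodingConfig(
                    temperature=temp,
                    top_k=top_k,
                    top_p=top_p,
                    num_return_sequences=run.n_structures,
                    multiplier=run.multiplier,
                    seed=(run.seed + 7919 * repeat + gi) & 0x7FFFFFFF,
                )
                try:
                    hypotheses = rank_hypotheses(
                        backend.aa_to_3di(fragment, cfg), run.alpha
                    )
                except Exception as exc:  # backend failure: keep partial results
                    errors.append(f"forward failure at {spec}: {exc}")
                    continue
                for rank, hyp in enumerate(hypotheses):
                    try:
                        recons = backend.di_to_aa(hyp.text, cfg)
                    except Exception as exc:
                        errors.append(f"backward failure at {spec} rank {rank}: {exc}")
                        continue
                    for bi, cand in enumerate(recons):
                        rows.append(
                            GeneratedRow(
                                sequence=cand.sequence,
                                fragment=spec,
                                grid_point=(temp, top_k, top_p),
                                forward_rank=rank,
                                backward_index=bi,
                                repeat=repeat,
                                forward_score=length_normalized_score(hyp, run.alpha),
                                backward_logprob=cand.cumulative_logprob,
                            )
                        )
    if not rows:
        raise RuntimeError(
            "generation produced zero rows"
            + (f" ({len(errors)} backend errors)" if errors else "")
        )
    if errors:
        import warnings

        warnings.warn(f"generation completed with {len(errors)} backend errors")
    return rows[:budget]
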