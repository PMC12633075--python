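"""Bilingual sequence<->structure translation backends.

The generative pipeline needs two sampling operations: forward structural
abstraction (amino acids -> 3Di structural tokens) and backward sequence
reconstruction (3Di -> amino acids).  Both are abstracted behind
:class:`TranslatorBackend` so the pipeline is agnostic to the underlying
model.  Two backends ship:

* :class:`MockTranslator` — a deterministic, seeded cipher-plus-noise
  backend for desk-scale runs and testing.  Its backward direction emits
  sequences whose identity to the cipher inverse is drawn uniformly from a
  configurable band, mimicking the controlled divergence a structure-
  conditioned language model produces.
* :class:`ProstT5Adapter` — an optional adapter around the bilingual
  protein language model (requires the ``plm`` extra); it owns the
  ``<AA2fold>``/``<fold2AA>`` prompt conventions internally.
"""

from __future__ import annotations

import abc
import warnings
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .alphabets import (
    AA_ALPHABET,
    TDI_ALPHABET,
    AlphabetError,
    AminoSequence,
    StructuralString,
)

__all__ = [
    "DecodingConfig",
    "ScoredCandidate",
    "TranslatorBackend",
    "MockTranslator",
    "ProstT5Adapter",
    "get_backend",
    "BackendError",
    "ConfigError",
]


class BackendError(RuntimeError):
    """The translation backend is unavailable or failed mid-call."""


class ConfigError(ValueError):
    """Invalid decoding or backend configuration."""


@dataclass(frozen=True)
class DecodingConfig:
    """Stochastic decoding controls shared by both translation directions.

    Parameters mirror the usual language-model sampling knobs: temperature
    ``T`` rescales logits, ``top_k``/``top_p`` truncate the sampling pool
    (they may be combined, as in standard nucleus+top-k composition),
    ``num_return_sequences`` (N) is the number of forward structural
    hypotheses, ``multiplier`` (M) the backward sampling depth per
    hypothesis, and ``beam_width`` the number of beams kept in the forward
    stochastic beam search.
    """

    temperature: float = 1.0
    top_k: Optional[int] = None
    top_p: Optional[float] = None
    num_return_sequences: int = 1
    multiplier: int = 1
    beam_width: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ConfigError("temperature must be >= 0")
        if self.top_k is not None and self.top_k < 1:
            raise ConfigError("top_k must be a positive integer")
        if self.top_p is not None and not (0 < self.top_p <= 1):
            raise ConfigError("top_p must lie in (0, 1]")
        if self.num_return_sequences < 1 or self.multiplier < 1:
            raise ConfigError("N and M must be >= 1")
        if self.beam_width < 1:
            raise ConfigError("beam_width must be >= 1")


@dataclass(frozen=True)
class ScoredCandidate:
    """A generated token string with its per-token log-probabilities."""

    text: Union[AminoSequence, StructuralString]
    token_logprobs: tuple
    cumulative_logprob: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lps = tuple(float(x) for x in self.token_logprobs)
        object.__setattr__(self, "token_logprobs", lps)
        if any(lp > 1e-12 for lp in lps):
            raise ConfigError("token log-probabilities must be <= 0")
        if len(lps) != len(self.text):
            raise ConfigError("one log-probability per token required")
        total = float(sum(lps))
        if self.cumulative_logprob is None:
            object.__setattr__(self, "cumulative_logprob", total)
        elif abs(self.cumulative_logprob - total) > 1e-9:
            raise ConfigError("cumulative_logprob must equal the sum of token_logprobs")

    @property
    def sequence(self) -> str:
        t = self.text
        return t.residues if isinstance(t, AminoSequence) else t.tokens

    def __len__(self) -> int:
        return len(self.text)


class TranslatorBackend(abc.ABC):
    """Uniform sampling interface over AA->3Di and 3Di->AA translation."""

    name: str = "abstract"

    @abc.abstractmethod
    def aa_to_3di(
        self, fragment: AminoSequence, cfg: DecodingConfig
    ) -> List[ScoredCandidate]:
        """Sample up to N distinct structural hypotheses for ``fragment``.

        Each candidate is a :class:`StructuralString` of exactly the
        fragment's length, with per-token log-probabilities attached.
        Exact duplicates are removed after generation.
        """

    @abc.abstractmethod
    def di_to_aa(
        self, structure: StructuralString, cfg: DecodingConfig
    ) -> List[ScoredCandidate]:
        """Multinomially sample up to M amino-acid reconstructions."""


def _dedupe(cands: List[ScoredCandidate], requested: int) -> List[ScoredCandidate]:
    seen: set = set()
    out: List[ScoredCandidate] = []
    for c in cands:
        if c.sequence not in seen:
            seen.add(c.sequence)
            out.append(c)
    if requested > 1 and len(out) == 1:
        warnings.warn(
            "all generated candidates collapsed to a single string",
            stacklevel=3,
        )
    return out


class MockTranslator(TranslatorBackend):
    """Deterministic cipher-based stand-in for the bilingual language model.

    Forward direction: a seeded position-dependent substitution cipher maps
    each amino acid to a 3Di token, then per-position noise (rate scaling
    linearly with temperature, so the T->0 limit is the exact cipher) emits
    alternative tokens.  Backward direction: the cipher is inverted, then
    seeded substitutions push the emitted sequence's identity to the cipher
    inverse to a value drawn uniformly from ``identity_band`` — emulating
    the 30-50% identity-to-query divergence a structure-conditioned
    generator realises.  Token log-probabilities are the logs of the
    per-position emission probabilities actually used, so likelihood
    bookkeeping is exact.

    Fully deterministic under a fixed (input, config, seed) triple.
    """

    name = "mock"

    def __init__(
        self,
        seed: int = 0,
        identity_band: tuple = (0.3, 0.5),
        forward_noise: float = 0.05,
    ) -> None:
        low, high = identity_band
        if not (0 < low <= high <= 1):
            raise ConfigError("identity_band must satisfy 0 < low <= high <= 1")
        if not (0 <= forward_noise <= 1):
            raise ConfigError("forward_noise must lie in [0, 1]")
        self.seed = int(seed)
        self.identity_band = (float(low), float(high))
        self.forward_noise = float(forward_noise)
        base = np.random.default_rng(self.seed).permutation(20)
        self._perm = base  # AA index -> 3Di index offset table
        self._inv = np.argsort(base)

    # -- cipher ---------------------------------------------------------
    def _cipher_forward(self, residues: str) -> str:
        out = []
        for i, ch in enumerate(residues):
            a = AA_ALPHABET.index(ch)
            out.append(TDI_ALPHABET[(self._perm[a] + i) % 20])
        return "".join(out)

    def _cipher_backward(self, tokens: str) -> str:
        out = []
        for i, ch in enumerate(tokens):
            d = (TDI_ALPHABET.index(ch) - i) % 20
            out.append(AA_ALPHABET[self._inv[d]])
        return "".join(out)

    def _rng(self, payload: str, cfg: DecodingConfig, tag: str, k: int) -> np.random.Generator:
        h = zlib.crc32(payload.encode())
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, cfg.seed & 0x7FFFFFFF, h, zlib.crc32(tag.encode()), k])
        )

    # -- forward --------------------------------------------------------
    def aa_to_3di(
        self, fragment: AminoSequence, cfg: DecodingConfig
    ) -> List[ScoredCandidate]:
        base = self._cipher_forward(fragment.residues)
        rate = min(1.0, self.forward_noise * cfg.temperature)
        cands: List[ScoredCandidate] = []
        for k in range(cfg.num_return_sequences):
            rng = self._rng(fragment.residues, cfg, "fwd", k)
            toks, lps = self._emit(base, TDI_ALPHABET, rate, rng)
            cands.append(
                ScoredCandidate(StructuralString(toks), tuple(lps))
            )
        return _dedupe(cands, cfg.num_return_sequences)

    # -- backward -------------------------------------------------------
    def di_to_aa(
        self, structure: StructuralString, cfg: DecodingConfig
    ) -> List[ScoredCandidate]:
        base = self._cipher_backward(structure.tokens)
        n = len(base)
        low, high = self.identity_band
        cands: List[ScoredCandidate] = []
        for k in range(cfg.multiplier):
            rng = self._rng(structure.tokens, cfg, "bwd", k)
            if cfg.temperature < 1e-9:
                n_sub = 0
            else:
                target = rng.uniform(low, high)
                n_sub = int(round((1.0 - target) * n))
            toks, lps = self._emit_exact(base, AA_ALPHABET, n_sub, rng)
            cands.append(ScoredCandidate(AminoSequence(toks, id="mock"), tuple(lps)))
        return _dedupe(cands, cfg.multiplier)

    # -- emission helpers ----------------------------------------------
    @staticmethod
    def _emit(base: str, alphabet: str, rate: float, rng: np.random.Generator):
        """Bernoulli(rate) substitution per position, uniform over the 19
        alternatives; log-probs reflect the emission model used."""
        toks, lps = [], []
        for ch in base:
            if rate > 0 and rng.random() < rate:
                alt = [c for c in alphabet if c != ch]
                toks.append(alt[rng.integers(len(alt))])
                lps.append(float(np.log(rate / 19.0)))
            else:
                toks.append(ch)
                lps.append(float(np.log(1.0 - rate)) if rate > 0 else 0.0)
        return "".join(toks), lps

    @staticmethod
    def _emit_exact(base: str, alphabet: str, n_sub: int, rng: np.random.Generator):
        """Substitute exactly ``n_sub`` positions chosen without replacement."""
        n = len(base)
        positions = set(rng.choice(n, size=n_sub, replace=False).tolist()) if n_sub else set()
        p_sub = n_sub / n
        toks, lps = [], []
        for i, ch in enumerate(base):
            if i in positions:
                alt = [c for c in alphabet if c != ch]
                toks.append(alt[rng.integers(len(alt))])
                lps.append(float(np.log(p_sub / 19.0)))
            else:
                toks.append(ch)
                lps.append(float(np.log(1.0 - p_sub)) if p_sub > 0 else 0.0)
        return "".join(toks), lps

    # -- convenience ----------------------------------------------------
    def generate(
        self,
        payload: Union[AminoSequence, StructuralString],
        direction: str,
        cfg: DecodingConfig,
    ) -> List[ScoredCandidate]:
        """Dispatch on direction: 'forward' = AA->3Di, 'backward' = 3Di->AA."""
        if direction == "forward":
            if not isinstance(payload, AminoSequence):
                raise AlphabetError("forward direction expects an AminoSequence")
            return self.aa_to_3di(payload, cfg)
        if direction == "backward":
            if not isinstance(payload, StructuralString):
                raise AlphabetError("backward direction expects a StructuralString")
            return self.di_to_aa(payload, cfg)
        raise ConfigError(f"unknown direction {direction!r}")


class ProstT5Adapter(TranslatorBackend):
    """Adapter for the bilingual AA<->3Di protein language model.

    Requires the optional ``plm`` extra (transformers + torch).  The
    ``<AA2fold>``/``<fold2AA>`` prompt formats and the model's lowercase
    3Di convention are handled here; the rest of the package sees only
    uppercase token strings.
    """

    name = "prostt5"

    def __init__(self, model_name: str = "Rostlab/ProstT5", device: str = "cpu") -> None:
        try:
            import torch  # noqa: F401
            from transformers import AutoTokenizer, T5ForConditionalGeneration  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise BackendError(
                "the protein-language-model backend requires the 'plm' extra "
                "(pip install pseudomsa[plm])"
            ) from exc
        self._model_name = model_name
        self._device = device
        self._loaded = False

    def _load(self):  # pragma: no cover - requires model download
        from transformers import AutoTokenizer, T5ForConditionalGeneration

        self._tok = AutoTokenizer.from_pretrained(self._model_name, do_lower_case=False)
        self._model = T5ForConditionalGeneration.from_pretrained(self._model_name).to(
            self._device
        )
        self._loaded = True

    def _generate(self, prompt: str, cfg: DecodingConfig, n: int, beams: bool):  # pragma: no cover
        import torch

        if not self._loaded:
            self._load()
        torch.manual_seed(cfg.seed)
        spaced = " ".join(prompt)
        ids = self._tok(spaced, return_tensors="pt").to(self._device)
        kwargs = dict(
            max_new_tokens=len(prompt) + 1,
            min_new_tokens=len(prompt) + 1,
            num_return_sequences=n,
            do_sample=True,
            temperature=cfg.temperature,
            output_scores=True,
            return_dict_in_generate=True,
        )
        if cfg.top_k is not None:
            kwargs["top_k"] = cfg.top_k
        if cfg.top_p is not None:
            kwargs["top_p"] = cfg.top_p
        if beams:
            kwargs["num_beams"] = max(cfg.beam_width, n)
        out = self._model.generate(**ids, **kwargs)
        scores = self._model.compute_transition_scores(
            out.sequences, out.scores, normalize_logits=True
        )
        results = []
        for seq, sc in zip(out.sequences, scores):
            text = self._tok.decode(seq, skip_special_tokens=True).replace(" ", "")
            lps = tuple(min(float(x), 0.0) for x in sc[: len(text)])
            results.append((text.upper(), lps))
        return results

    def aa_to_3di(self, fragment, cfg):  # pragma: no cover - requires model
        raw = self._generate(
            "<AA2fold> " + fragment.residues, cfg, cfg.num_return_sequences, beams=True
        )
        cands = [
            ScoredCandidate(StructuralString(t[: len(fragment)]), lp[: len(fragment)])
            for t, lp in raw
            if len(t) >= len(fragment)
        ]
        return _dedupe(cands, cfg.num_return_sequences)

    def di_to_aa(self, structure, cfg):  # pragma: no cover - requires model
        raw = self._generate(
            "<fold2AA> " + structure.tokens.lower(), cfg, cfg.multiplier, beams=False
        )
        cands = [
            ScoredCandidate(AminoSequence(t[: len(structure)], id="plm"), lp[: len(structure)])
            for t, lp in raw
            if len(t) >= len(structure)
        ]
        return _dedupe(cands, cfg.multiplier)


_BACKENDS = {"mock": MockTranslator, "prostt5": ProstT5Adapter}


def get_backend(name: str, **kwargs) -> TranslatorBackend:
    """Instantiate a registered backend by config key."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ConfigError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)
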