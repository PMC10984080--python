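"""Synthetic admission-note corpora with known ground truth.

Real psychiatric admission notes cannot be shared, so every pipeline stage is
exercised on generated corpora that reproduce the *statistical structure* the
analysis relies on, with full ground truth attached:

* section-structured notes (history of present illness, past psychiatric
  history, family history, formulation);
* class-conditional keyword emission: per tier, the number of keyword-bearing
  sentences in a note is Poisson with a case rate and a (lower) control rate;
  each such sentence embeds one lexicon term, optionally wrapped in a negation
  frame ("No signs of …", "Denies …") — negated mentions still contain the
  term, which is precisely the substring-matching failure mode being studied;
* filler text drawn from a Zipf-weighted nonsense vocabulary that is
  *provably* unable to produce a keyword match (every generated word is
  filtered against all lexicon terms and all constituent words of multi-word
  terms, so matches cannot arise even across token boundaries);
* PHI-like spans (dates, clinician and hospital names, street addresses, long
  numbers) injected at known positions;
* a long-tailed log-normal note-length distribution on the whitespace-token
  scale;
* discharge ICD codes that agree with the true label with configurable
  accuracy.

The companion :func:`bayes_optimal_auroc` computes, from the emission model
alone, the AUROC of the likelihood-ratio classifier on the per-tier keyword
counts — the ceiling any text classifier can reach on these corpora — by
exact enumeration (or Monte Carlo for high-dimensional configurations).

The generated language is deliberately artificial: these corpora validate the
pipeline's mechanics and statistical behaviour, not clinical language models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import poisson

from .lexicon import _read_packaged_rows, load_packaged_lexicon
from .textprep import Note

__all__ = ["SynthConfig", "SynthNote", "KeywordSpan", "PhiSpan", "generate_corpus", "bayes_optimal_auroc"]

PAPER_PREVALENCE = 1196 / 4629  # cohort case fraction the default profile emulates

# --- filler vocabulary --------------------------------------------------------

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu ka ke ki ko ku "
    "la le li lo lu ma me mi mo na ne ni no nu pa pe pi po pu ra re ri ro ru "
    "sa se si so su ta te ti to tu va ve vi vo vu wa we wi wo za ze zi zo zu"
).split()

# Real-word head of the vocabulary: common clinical-note filler. Each word still
# passes the lexicon-disjointness filter below before use.
_COMMON_FILLER = (
    "patient reports sleep appetite energy concentration school work stress family "
    "supportive outpatient therapy medication plan safety discharge follow visit "
    "weeks days described improved worsening symptoms denies use alcohol cannabis "
    "friends college living home parents sister brother teacher exam anxiety low "
    "stable calm cooperative pleasant engaged goal oriented future treatment team "
    "daily routine appetite eating sleeping nightmares difficulty start semester"
).split()


def _forbidden_substrings() -> list[str]:
    """Every lexicon term plus each constituent word of multi-word terms.

    A filler word containing any of these could create a keyword match, either
    directly or across a token boundary (e.g. a word ending in "loose" next to
    one starting with "association"), so all are banned from the vocabulary.
    """
    lex = load_packaged_lexicon("all")
    forbidden: set[str] = set()
    for term in lex.terms:
        forbidden.add(term)
        forbidden.update(term.split())
    return sorted(forbidden)


def _make_filler_vocab(size: int = 1200, internal_seed: int = 987654321) -> list[str]:
    """Deterministic nonsense vocabulary, disjoint from all keyword material."""
    forbidden = _forbidden_substrings()

    def ok(w: str) -> bool:
        return not any(f in w for f in forbidden)

    vocab = [w for w in dict.fromkeys(_COMMON_FILLER) if ok(w)]
    rng = np.random.default_rng(internal_seed)
    seen = set(vocab)
    while len(vocab) < size:
        w = "".join(rng.choice(_SYLLABLES, size=rng.integers(2, 5)))
        if w not in seen and ok(w):
            seen.add(w)
            vocab.append(w)
    return vocab


_FILLER_VOCAB: list[str] | None = None
_FILLER_PROBS: np.ndarray | None = None


def _filler() -> tuple[list[str], np.ndarray]:
    global _FILLER_VOCAB, _FILLER_PROBS
    if _FILLER_VOCAB is None:
        _FILLER_VOCAB = _make_filler_vocab()
        ranks = np.arange(1, len(_FILLER_VOCAB) + 1, dtype=float)
        p = ranks**-1.1  # Zipf-ish: common head, long informative-noise tail
        _FILLER_PROBS = p / p.sum()
    return _FILLER_VOCAB, _FILLER_PROBS


# --- note templates -----------------------------------------------------------

SECTIONS = (
    "History of Present Illness:",
    "Past Psychiatric History:",
    "Family History:",
    "Formulation:",
)

_KEYWORD_FRAMES = (
    "Patient endorses {term}.",
    "Exam notable for {term}.",
    "Collateral describes {term} this week.",
    "Clinical picture includes {term}.",
)
_NEGATION_FRAMES = (
    "No signs of {term}.",
    "Denies {term}.",
    "Patient denies any {term}.",
    "No evidence of {term} on exam.",
)

_SURNAMES = ("Alvarez", "Brennan", "Chukwu", "Dimitriou", "Ellison", "Fontaine", "Garza", "Hargrove")
_PLACES = ("Lakeview", "Northgate", "Riverbend", "Stonebridge", "Westfield", "Maplecrest")
_STREETS = ("Birchwood", "Camden", "Fenwick", "Juniper", "Oakhurst", "Willow")

_CASE_ICD = ("F23", "F20.9", "F25.0", "F29", "F12.15", "F28")
_CONTROL_ICD = ("F32.9", "F41.1", "F43.10", "F60.3", "F90.0", "F50.9")


# --- configuration ------------------------------------------------------------


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of a synthetic corpus.

    ``emission_rates`` maps lexicon tier -> (case rate, control rate): the
    Poisson mean number of keyword sentences of that tier per note, by class.
    ``negation_rate`` is the probability that a keyword sentence uses a
    negation frame. Note length (whitespace tokens) follows a log-normal with
    parameters ``length_log_mean``/``length_log_sd``; by default filler
    sentences are generated until the drawn token budget is met. Setting
    ``noise_sentence_rate`` overrides that: the filler sentence count is then
    Poisson with this mean and the length target is ignored (used for
    high-noise pre-selection experiments). ``guarantee_base_keyword`` forces
    every note (both classes) to carry at least one base keyword sentence, the
    regime observed in the real cohort. ``icd_accuracy`` is the probability
    that the injected discharge code agrees with the true label.
    """

    n_notes: int = 1000
    prevalence: float = PAPER_PREVALENCE
    emission_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"base": (4.0, 0.4), "strict": (1.0, 0.1), "broad": (1.2, 0.6)}
    )
    negation_rate: float = 0.15
    noise_sentence_rate: float | None = None
    phi_rate: float = 2.0
    length_log_mean: float = 6.5
    length_log_sd: float = 0.7
    guarantee_base_keyword: bool = True
    icd_accuracy: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 1:
            raise ValueError("n_notes must be >= 1")
        for name in ("prevalence", "negation_rate", "icd_accuracy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for tier, (rc, r0) in self.emission_rates.items():
            if tier not in ("base", "strict", "broad"):
                raise ValueError(f"unknown emission tier {tier!r}")
            if rc < 0 or r0 < 0:
                raise ValueError(f"emission rates must be >= 0, got {tier}: ({rc}, {r0})")
        if self.phi_rate < 0:
            raise ValueError("phi_rate must be >= 0")
        if self.noise_sentence_rate is not None and self.noise_sentence_rate < 0:
            raise ValueError("noise_sentence_rate must be >= 0")
        if self.length_log_sd <= 0:
            raise ValueError("length_log_sd must be > 0")

    # -- named study profiles --------------------------------------------------

    @classmethod
    def paper_like(cls, n_notes: int = 5000, seed: int = 0) -> "SynthConfig":
        """The default cohort-emulating regime: prevalence 1196/4629, every
        note base-keyword-positive, log-normal lengths, negation present."""
        return cls(n_notes=n_notes, seed=seed)

    @classmethod
    def poisson_recovery(cls, n_notes: int = 2000, seed: int = 0) -> "SynthConfig":
        """Single-tier Poisson emission (base: 2.0 vs 0.5) with short notes and
        no base-keyword guarantee, so the Bayes-optimal AUROC of the keyword
        count model is an exact enumeration target for parameter recovery."""
        return cls(
            n_notes=n_notes,
            emission_rates={"base": (2.0, 0.5)},
            negation_rate=0.0,
            guarantee_base_keyword=False,
            length_log_mean=5.0,
            length_log_sd=0.4,
            phi_rate=1.0,
            seed=seed,
        )

    @classmethod
    def high_noise(cls, n_notes: int = 1500, seed: int = 0) -> "SynthConfig":
        """Heavy filler regime for the pre-selection experiments: ~80 filler
        sentences per note drowning a moderate keyword signal."""
        return cls(
            n_notes=n_notes,
            emission_rates={"base": (2.0, 0.8)},
            negation_rate=0.15,
            noise_sentence_rate=80.0,
            guarantee_base_keyword=False,
            phi_rate=1.0,
            seed=seed,
        )


@dataclass(frozen=True)
class KeywordSpan:
    term: str
    tier: str
    negated: bool
    start: int
    end: int


@dataclass(frozen=True)
class PhiSpan:
    kind: str  # date | doctor | hospital | address | number
    surface: str
    start: int
    end: int


@dataclass
class SynthNote(Note):
    """A generated note plus its ground truth channels."""

    keyword_spans: list[KeywordSpan] = field(default_factory=list)
    phi_spans: list[PhiSpan] = field(default_factory=list)
    sentence_spans: list[tuple[int, int]] = field(default_factory=list)


# --- generation ---------------------------------------------------------------


def _phi_sentence(rng: np.random.Generator) -> tuple[str, list[tuple[str, str]]]:
    """One PHI-bearing sentence and its (kind, surface) payloads."""
    kind = rng.choice(("date", "doctor", "hospital", "address", "number"))
    if kind == "date":
        surface = f"{rng.integers(1, 13):02d}/{rng.integers(1, 29):02d}/{rng.integers(2005, 2020)}"
        return f"Initial evaluation completed on {surface}.", [("date", surface)]
    if kind == "doctor":
        surface = f"Dr. {rng.choice(_SURNAMES)}"
        return f"Seen in consultation by {surface}.", [("doctor", surface)]
    if kind == "hospital":
        surface = f"{rng.choice(_PLACES)} Hospital"
        return f"Transferred from {surface} for further care.", [("hospital", surface)]
    if kind == "address":
        surface = f"{rng.integers(1, 999)} {rng.choice(_STREETS)} Street"
        return f"Resides at {surface} with roommates.", [("address", surface)]
    surface = str(rng.integers(10**6, 10**8))
    return f"Record number {surface} reviewed.", [("number", surface)]


def _filler_sentence(words: np.ndarray, lo: int, hi: int) -> tuple[str, int]:
    n = hi - lo
    toks = words[lo:hi]
    return toks[0].capitalize() + " " + " ".join(toks[1:]) + ".", n


def generate_corpus(config: SynthConfig) -> list[SynthNote]:
    """Generate a labelled corpus with ground-truth spans; seed-reproducible."""
    rng = np.random.default_rng(config.seed)
    # per-tier term pools (strict/broad pools exclude lower-tier columns)
    all_rows: dict[str, list[str]] = {"base": [], "strict": [], "broad": []}
    for term, tier in _read_packaged_rows():
        all_rows[tier].append(term)
    pools = {
        t: np.asarray(list(dict.fromkeys(v)), dtype=object) for t, v in all_rows.items()
    }
    vocab, probs = _filler()
    vocab_arr = np.asarray(vocab, dtype=object)

    notes: list[SynthNote] = []
    for i in range(config.n_notes):
        label: Literal["case", "control"] = (
            "case" if rng.random() < config.prevalence else "control"
        )
        col = 0 if label == "case" else 1

        # keyword sentences: (sentence, term, tier, negated, term offset in sentence)
        kw_sentences: list[tuple[str, str, str, bool]] = []
        for tier, rates in config.emission_rates.items():
            k = rng.poisson(rates[col])
            if tier == "base" and config.guarantee_base_keyword and k == 0:
                k = 1
            for _ in range(k):
                term = str(rng.choice(pools[tier]))
                negated = bool(rng.random() < config.negation_rate)
                frames = _NEGATION_FRAMES if negated else _KEYWORD_FRAMES
                frame = frames[int(rng.integers(0, len(frames)))]
                kw_sentences.append((frame.format(term=term), term, tier, negated))

        phi_sentences = [_phi_sentence(rng) for _ in range(rng.poisson(config.phi_rate))]

        base_tokens = sum(len(s.split()) for s, *_ in kw_sentences)
        base_tokens += sum(len(s.split()) for s, _ in phi_sentences)
        base_tokens += sum(len(h.split()) for h in SECTIONS)

        # filler sentence plan: word counts per sentence
        if config.noise_sentence_rate is not None:
            n_fill = int(rng.poisson(config.noise_sentence_rate))
            lens = rng.integers(5, 12, size=n_fill) if n_fill else np.empty(0, dtype=int)
        else:
            budget = float(rng.lognormal(config.length_log_mean, config.length_log_sd))
            need = max(0.0, budget - base_tokens)
            lens_list: list[int] = []
            got = 0.0
            while got < need:
                ln = int(rng.integers(5, 12))
                lens_list.append(ln)
                got += ln
            lens = np.asarray(lens_list, dtype=int)
        total_fill = int(lens.sum())
        fill_words = (
            rng.choice(vocab_arr, size=total_fill, p=probs)
            if total_fill
            else np.empty(0, dtype=object)
        )
        offsets = np.concatenate([[0], np.cumsum(lens)])
        filler_sentences = [
            _filler_sentence(fill_words, offsets[j], offsets[j + 1])[0] for j in range(len(lens))
        ]

        # distribute sentences over the four sections
        sec_payload: list[list[tuple[str, object]]] = [[] for _ in SECTIONS]
        for s, term, tier, negated in kw_sentences:
            # symptom content concentrates in HPI and formulation
            sec = int(rng.choice((0, 0, 0, 3)))
            sec_payload[sec].append((s, ("kw", term, tier, negated)))
        for s, payloads in phi_sentences:
            sec = int(rng.integers(0, len(SECTIONS)))
            sec_payload[sec].append((s, ("phi", payloads)))
        for j, s in enumerate(filler_sentences):
            sec_payload[j % len(SECTIONS)].append((s, None))
        for payload in sec_payload:
            rng.shuffle(payload)

        # assemble text, tracking global character spans
        parts: list[str] = []
        pos = 0
        kw_spans: list[KeywordSpan] = []
        phi_spans: list[PhiSpan] = []
        sent_spans: list[tuple[int, int]] = []

        def _append(s: str) -> int:
            nonlocal pos
            start = pos
            parts.append(s)
            pos += len(s)
            sent_spans.append((start, start + len(s)))
            return start

        for header, payload in zip(SECTIONS, sec_payload):
            if parts:
                parts.append("\n\n")
                pos += 2
            _append(header)
            for j, (s, meta) in enumerate(payload):
                # header stays on its own line; sentences are space-joined
                parts.append("\n" if j == 0 else " ")
                pos += 1
                start = _append(s)
                if meta is None:
                    continue
                if meta[0] == "kw":
                    _, term, tier, negated = meta
                    off = s.lower().index(term)
                    kw_spans.append(
                        KeywordSpan(term, tier, negated, start + off, start + off + len(term))
                    )
                else:
                    for kind, surface in meta[1]:
                        off = s.index(surface)
                        phi_spans.append(
                            PhiSpan(kind, surface, start + off, start + off + len(surface))
                        )

        text = "".join(parts)

        # discharge codes agree with the label at the configured accuracy
        agrees = rng.random() < config.icd_accuracy
        effective = label if agrees else ("control" if label == "case" else "case")
        pool = _CASE_ICD if effective == "case" else _CONTROL_ICD
        icd = [str(rng.choice(np.asarray(pool, dtype=object)))]

        notes.append(
            SynthNote(
                note_id=f"synth-{config.seed}-{i:05d}",
                text=text,
                icd_codes=icd,
                label=label,
                keyword_spans=kw_spans,
                phi_spans=phi_spans,
                sentence_spans=sent_spans,
            )
        )
    return notes


# --- Bayes-optimal AUROC of the emission model --------------------------------


def _tier_pmfs(config: SynthConfig, cap_quantile: float = 1 - 1e-10):
    """Per-tier count pmfs (case, control) over a shared finite support."""
    out = []
    for tier, (rc, r0) in config.emission_rates.items():
        if rc == 0 and r0 == 0:
            continue
        cap = int(poisson.ppf(cap_quantile, max(rc, r0, 1e-12))) + 2
        ks = np.arange(cap + 1)
        pc = poisson.pmf(ks, rc) if rc > 0 else (ks == 0).astype(float)
        p0 = poisson.pmf(ks, r0) if r0 > 0 else (ks == 0).astype(float)
        if tier == "base" and config.guarantee_base_keyword:
            # zero counts are promoted to one for every note
            pc = pc.copy()
            p0 = p0.copy()
            pc[1] += pc[0]
            p0[1] += p0[0]
            pc[0] = p0[0] = 0.0
        pc, p0 = pc / pc.sum(), p0 / p0.sum()
        out.append((np.log(np.maximum(pc, 1e-300)), np.log(np.maximum(p0, 1e-300))))
    return out


def bayes_optimal_auroc(
    config: SynthConfig,
    mc_samples: int = 400_000,
    seed: int = 0,
    return_se: bool = False,
    method: Literal["auto", "exact", "mc"] = "auto",
):
    """AUROC of the likelihood-ratio classifier on per-tier keyword counts.

    This is the information ceiling of the generator's emission model: the
    observable is the vector of per-tier keyword-sentence counts, the score is
    its log likelihood ratio, and ties count half. Exact enumeration over the
    joint count support is used when feasible (≤ ~2M cells); otherwise Monte
    Carlo with ``mc_samples`` draws per class, whose standard error is
    available via ``return_se``.
    """
    pmfs = _tier_pmfs(config)
    if not pmfs:
        return (0.5, 0.0) if return_se else 0.5
    sizes = [len(pc) for pc, _ in pmfs]
    n_cells = math.prod(sizes)
    if method == "exact" and n_cells > 50_000_000:
        raise ValueError(f"joint support too large for exact enumeration ({n_cells} cells)")
    if method != "mc" and n_cells <= 2_000_000:
        log_pc = np.zeros(1)
        log_p0 = np.zeros(1)
        for pc, p0 in pmfs:
            log_pc = (log_pc[:, None] + pc[None, :]).ravel()
            log_p0 = (log_p0[:, None] + p0[None, :]).ravel()
        llr = log_pc - log_p0
        order = np.argsort(llr, kind="stable")
        llr, wc, w0 = llr[order], np.exp(log_pc[order]), np.exp(log_p0[order])
        # group ties on the LLR scale
        boundaries = np.nonzero(np.abs(np.diff(llr)) > 1e-12)[0] + 1
        groups = np.split(np.arange(len(llr)), boundaries)
        cum0 = 0.0
        auc = 0.0
        for g in groups:
            gc, g0 = wc[g].sum(), w0[g].sum()
            auc += gc * cum0 + 0.5 * gc * g0
            cum0 += g0
        value = float(auc)
        return (value, 0.0) if return_se else value
    # Monte Carlo fallback for high-dimensional supports
    rng = np.random.default_rng(seed)
    draws = {}
    for cls in (0, 1):  # 0 = case column of the llr, 1 = control
        llr_sum = np.zeros(mc_samples)
        for pc, p0 in pmfs:
            p = np.exp(pc if cls == 0 else p0)
            ks = rng.choice(len(p), size=mc_samples, p=p)
            llr_sum += pc[ks] - p0[ks]
        draws[cls] = llr_sum
    from scipy.stats import rankdata

    s = np.concatenate([draws[0], draws[1]])
    r = rankdata(s)
    n1 = n0 = mc_samples
    value = float((r[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    se = float(np.sqrt(value * (1 - value) / min(n1, n0)))
    return (value, se) if return_se else value
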