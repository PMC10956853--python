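"""Finding-sentence generation from content sets.

A sequence-to-sequence LSTM with Luong *general* attention maps a canonical
ordering of the content tokens (segment placeholder, size placeholder,
opacity, then findings in category order) to a finding sentence containing
the ``<SEG>``/``<SIZE>`` placeholders, which are substituted with the actual
segment name and measurement afterwards.  Decoding is greedy, so generation
is deterministic for a trained model.

The corpus-side utilities mirror the report-editing pipeline: surface text
is normalized (size measurements → ``<SIZE>``, anatomy → ``<SEG>``, finding
terms canonicalized, other words dropped but flagged), and an iterative
augmentation step generates sentences for unseen content combinations,
keeping only those that pass both the adequacy check (the sentence inverts
to exactly its input contents) and the fluency check (grammar membership).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grammar import (
    CONTENT_ORDER,
    SEG_TOKEN,
    SIZE_TOKEN,
    GrammarConfig,
    extract_contents,
    is_grammatical,
    order_contents,
)
from .nn import Adam, LSTMCell, Linear, Module, Tensor, concat, stack

__all__ = [
    "GenTrainConfig",
    "Seq2SeqGenerator",
    "TrainedGenerator",
    "encode_contents",
    "normalize_report_text",
    "NormalizedText",
    "train_generator",
    "continue_training",
    "save_generator",
    "load_generator",
    "generate_description",
    "substitute_tokens",
    "augment_corpus_iteration",
]

PAD, SOS, EOS = "<PAD>", "<SOS>", "<EOS>"


def encode_contents(contents: frozenset[str] | set[str]) -> list[str]:
    """Canonical, injective token sequence for a content set."""
    return order_contents(contents)


# ---------------------------------------------------------------------------
# report-text normalization
# ---------------------------------------------------------------------------

_SIZE_RE = re.compile(r"\b\d+(\.\d+)?\s*mm\b")
_SEG_RE = re.compile(r"\b(the\s+)?(right|left)\s+(S\d+|(upper|middle|lower)\s+lobe)\b")

#: function words of the surrogate grammar that survive normalization
KEEP_WORDS = {
    "a", "an", "in", "nodule", "mass", "is", "seen", "noted", "showing",
    "and", "with", ",", ".",
}


#: bare adjective/noun forms accepted as content in free report text, in
#: addition to the grammar's own phrases; each canonicalizes to itself
_BARE_FORMS = (
    "spiculated", "lobulated", "ragged", "polygonal", "ill-defined",
    "well-defined", "calcified", "cavitary", "subpleural",
)


def _default_normalize_lexicon() -> dict[str, tuple[str, ...]]:
    lex = {k: tuple(v) for k, v in GrammarConfig().lexicon.items()}
    for i, form in enumerate(_BARE_FORMS):
        lex[f"_bare_{i}"] = (form,)
    return lex


@dataclass(frozen=True)
class NormalizedText:
    text: str
    flags: tuple[str, ...] = ()  # dropped/unmappable words and warnings


def normalize_report_text(
    raw: str, lexicon: dict[str, tuple[str, ...]] | None = None
) -> NormalizedText:
    """Normalize one raw finding sentence.

    Size measurements become ``<SIZE>``, anatomy mentions become ``<SEG>``,
    finding phrases are canonicalized through `lexicon` (surface variant →
    canonical phrase, given as token → (canonical, *variants)), every other
    non-function word is removed and reported in ``flags``.  Deterministic
    and idempotent.
    """
    lexicon = lexicon or _default_normalize_lexicon()
    text = _SIZE_RE.sub(SIZE_TOKEN, raw)
    text = _SEG_RE.sub(SEG_TOKEN, text)
    text = re.sub(r"(?<! )([,.])", r" \1", text)  # free-standing punctuation
    words = text.split()
    # variant phrase (words) -> canonical phrase, longest first
    variants: list[tuple[tuple[str, ...], str]] = []
    for phrases in lexicon.values():
        canonical = phrases[0]
        for ph in phrases:
            variants.append((tuple(ph.split()), canonical))
        # bare adjective use: the token's words themselves stay valid content
    variants.sort(key=lambda kv: -len(kv[0]))
    out: list[str] = []
    flags: list[str] = []
    content_seen = False
    i = 0
    while i < len(words):
        w = words[i]
        if w in (SEG_TOKEN, SIZE_TOKEN):
            out.append(w)
            content_seen = True
            i += 1
            continue
        matched = False
        for phrase, canonical in variants:
            if tuple(words[i : i + len(phrase)]) == phrase:
                out.append(canonical)
                content_seen = True
                i += len(phrase)
                matched = True
                break
        if matched:
            continue
        if w in KEEP_WORDS:
            out.append(w)
        else:
            flags.append(f"dropped: {w}")
        i += 1
    if not content_seen:
        flags.append("empty-content")
    return NormalizedText(" ".join(out), tuple(flags))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class GenTrainConfig:
    embed_dim: int = 64
    hidden_dim: int = 128
    attention: str = "general"  # Luong-style bilinear score
    input_feeding: bool = False  # feed the attentional vector to the next step
    set_conditioning: bool = True  # expose the multi-hot content set per step
    max_len: int = 32
    teacher_forcing: float = 1.0
    epochs: int = 60
    batch_size: int = 32
    lr: float = 5e-3
    seed: int = 0

    def __post_init__(self):
        if self.attention != "general":
            raise ValueError("only the general (bilinear) attention is implemented")
        if not 0 <= self.teacher_forcing <= 1:
            raise ValueError("teacher_forcing must be in [0, 1]")


class Seq2SeqGenerator(Module):
    """Encoder LSTM over content tokens, decoder LSTM with general attention."""

    def __init__(self, vocab: list[str], config: GenTrainConfig):
        rng = np.random.default_rng(config.seed)
        self.vocab = list(vocab)
        self.stoi = {w: i for i, w in enumerate(self.vocab)}
        self.config = config
        v, e, h = len(vocab), config.embed_dim, config.hidden_dim

        def emb():
            t = Tensor((rng.normal(0, 0.1, (v, e))).astype(np.float32))
            t.requires_grad = True
            return t

        self.emb_in = emb()
        self.emb_out = emb()
        self.encoder = LSTMCell(e, h, rng)
        dec_in = e + h if config.input_feeding else e
        self.decoder = LSTMCell(dec_in, h, rng)
        self.w_att = Linear(h, h, rng)       # general attention: h_dec^T W h_enc
        self.n_set = len(CONTENT_ORDER) if config.set_conditioning else 0
        self.w_comb = Linear(2 * h + self.n_set, h, rng)  # tanh(W [ctx; h_dec; m])
        self.w_out = Linear(h, v, rng)

    # ---- helpers ---------------------------------------------------------
    def encode(self, ids: np.ndarray, lengths: np.ndarray | None = None):
        """ids: (B, L) right-padded; returns (states (B, L, H), h, c) where
        h and c are each item's state at its true last token, so padding
        never leaks into the decoder initialisation."""
        b, l = ids.shape
        h = Tensor(np.zeros((b, self.config.hidden_dim), dtype=np.float32))
        c = Tensor(np.zeros_like(h.data))
        hs, cs = [], []
        for t in range(l):
            x = self.emb_in[ids[:, t]]
            h, c = self.encoder(x, h, c)
            hs.append(h)
            cs.append(c)
        states = stack(hs, axis=1)
        if lengths is None:
            return states, hs[-1], cs[-1]
        rows = np.arange(b)
        last = np.asarray(lengths) - 1
        return states, states[rows, last], stack(cs, axis=1)[rows, last]

    def init_feed(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.config.hidden_dim), dtype=np.float32))

    def decode_step(self, prev_ids, h, c, enc_states, enc_mask, feed, set_vec=None):
        """One decoder step; returns (logits (B, V), h, c, attentional vector).

        `set_vec` is the multi-hot content vector (B, |CONTENT_ORDER|) that
        conditions phrase selection directly; the attention alone binds
        weakly at small corpus sizes and then hallucinates plausible-but-
        absent findings."""
        x = self.emb_out[prev_ids]
        if self.config.input_feeding:
            x = concat([x, feed], axis=1)
        h, c = self.decoder(x, h, c)
        keys = self.w_att(enc_states)                     # (B, L, H)
        score = (keys * h.reshape(h.shape[0], 1, h.shape[1])).sum(axis=2)
        score = score + Tensor(enc_mask)                  # -inf at pads
        score = score - score.max_detached(axis=1, keepdims=True)
        e = score.exp()
        alpha = e / e.sum(axis=1, keepdims=True)
        ctx = (alpha.reshape(alpha.shape + (1,)) * enc_states).sum(axis=1)
        parts = [ctx, h]
        if self.n_set:
            parts.append(set_vec)
        combined = self.w_comb(concat(parts, axis=1)).tanh()
        return self.w_out(combined), h, c, combined

    def set_vector(self, contents_list) -> Tensor:
        """Multi-hot encoding of content sets, (B, |CONTENT_ORDER|)."""
        m = np.zeros((len(contents_list), len(CONTENT_ORDER)), dtype=np.float32)
        for i, contents in enumerate(contents_list):
            for t in contents:
                m[i, CONTENT_ORDER.index(t)] = 1.0
        return Tensor(m)


@dataclass
class TrainedGenerator:
    model: Seq2SeqGenerator
    config: GenTrainConfig
    log: pd.DataFrame  # columns: epoch, train_loss, val_token_acc


def _build_vocab(pairs, grammar_words: set[str] | None = None) -> list[str]:
    words = set()
    for contents, sentence in pairs:
        words.update(contents)
        words.update(sentence.split())
    if grammar_words:
        words.update(grammar_words)
    return [PAD, SOS, EOS] + sorted(words)


def _ids(model: Seq2SeqGenerator, tokens: list[str]) -> list[int]:
    try:
        return [model.stoi[t] for t in tokens]
    except KeyError as exc:
        raise KeyError(f"unknown content token {exc.args[0]!r}") from None


def _prepare(model, pairs):
    xs = [_ids(model, encode_contents(c)) for c, _ in pairs]
    ys = [_ids(model, [SOS] + s.split() + [EOS]) for _, s in pairs]
    sets = model.set_vector([c for c, _ in pairs]).data
    return xs, ys, sets


def _pad_batch(seqs, pad_id, left=False):
    l = max(len(s) for s in seqs)
    out = np.full((len(seqs), l), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        if left:
            out[i, l - len(s):] = s
        else:
            out[i, : len(s)] = s
    return out


def train_generator(
    pairs, config: GenTrainConfig, val_pairs=(), grammar: GrammarConfig | None = None
) -> TrainedGenerator:
    """Train the generator; `pairs` and `val_pairs` must be disjoint on the
    content-set combination (a shared combination raises)."""
    if len(pairs) == 0:
        raise ValueError("empty training corpus")
    train_combos = {c for c, _ in pairs}
    leak = train_combos & {c for c, _ in val_pairs}
    if leak:
        raise ValueError(
            f"{len(leak)} content combination(s) shared between train and "
            "validation splits; splits must be disjoint on the combination"
        )
    longest = max(len(s.split()) for _, s in pairs) + 2
    if config.max_len < longest:
        raise ValueError(f"max_len {config.max_len} shorter than longest sentence ({longest})")
    g_words = set()
    if grammar is not None:
        for phrases in grammar.lexicon.values():
            for ph in phrases:
                g_words.update(ph.split())
    vocab = _build_vocab(list(pairs) + list(val_pairs), g_words)
    model = Seq2SeqGenerator(vocab, config)
    xs, ys, sets = _prepare(model, pairs)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    pad_id = model.stoi[PAD]
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(xs), config.batch_size):
            idx = order[start : start + config.batch_size]
            xi = [xs[i] for i in idx]
            xb = _pad_batch(xi, pad_id)
            yb = _pad_batch([ys[i] for i in idx], pad_id)
            lengths = np.array([len(s) for s in xi])
            loss = _batch_loss(
                model, xb, yb, pad_id, rng, config.teacher_forcing, sets[idx], lengths
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = (
            _token_accuracy(model, val_pairs) if len(val_pairs) else float("nan")
        )
        rows.append((epoch, float(np.mean(losses)), val_acc))
    log = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_token_acc"])
    return TrainedGenerator(model, config, log)


def _batch_loss(model, xb, yb, pad_id, rng, teacher_forcing, sets, lengths):
    b, l_out = yb.shape
    enc_states, h, c = model.encode(xb, lengths)
    enc_mask = np.where(xb == pad_id, -1e9, 0.0).astype(np.float32)
    set_vec = Tensor(sets)
    prev = yb[:, 0]
    feed = model.init_feed(b)
    steps = []
    for t in range(1, l_out):
        logits, h, c, feed = model.decode_step(
            prev, h, c, enc_states, enc_mask, feed, set_vec
        )
        target = yb[:, t]
        z = logits - logits.max_detached(axis=1, keepdims=True)
        lse = z.exp().sum(axis=1, keepdims=True).log()
        logp = z - lse
        nll = -logp[np.arange(b), target]
        w = (target != pad_id).astype(np.float32)
        steps.append((nll * Tensor(w)).sum() * (1.0 / max(w.sum(), 1.0)))
        if teacher_forcing >= 1.0 or rng.random() < teacher_forcing:
            prev = target
        else:
            prev = np.argmax(logits.data, axis=1)
    total = steps[0]
    for s in steps[1:]:
        total = total + s
    return total * (1.0 / len(steps))


def _token_accuracy(model_or_trained, pairs) -> float:
    """Greedy-decode token accuracy against reference sentences."""
    model = (
        model_or_trained.model
        if isinstance(model_or_trained, TrainedGenerator)
        else model_or_trained
    )
    n_ok = n_tot = 0
    for contents, ref in pairs:
        hyp = generate_description(model, contents).split()
        ref_w = ref.split()
        n_tot += len(ref_w)
        n_ok += sum(a == b for a, b in zip(hyp, ref_w))
    return n_ok / max(n_tot, 1)


def continue_training(
    trained: TrainedGenerator,
    pairs,
    epochs: int,
    seed: int | None = None,
    lr: float | None = None,
    teacher_forcing: float | None = None,
) -> TrainedGenerator:
    """Continue optimizing an existing generator on an (augmented) corpus.

    Used by the iterative self-augmentation loop: validated generated pairs
    are appended to the dataset and training resumes with a fresh optimizer.
    The vocabulary is fixed by the initial training run.
    """
    model, config = trained.model, trained.config
    tf = config.teacher_forcing if teacher_forcing is None else teacher_forcing
    xs, ys, sets = _prepare(model, pairs)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    opt = Adam(model.parameters(), lr=config.lr if lr is None else lr)
    pad_id = model.stoi[PAD]
    rows = []
    start_epoch = int(trained.log["epoch"].max()) + 1 if len(trained.log) else 0
    for epoch in range(epochs):
        order = rng.permutation(len(xs))
        losses = []
        for s0 in range(0, len(xs), config.batch_size):
            idx = order[s0 : s0 + config.batch_size]
            xi = [xs[i] for i in idx]
            xb = _pad_batch(xi, pad_id)
            yb = _pad_batch([ys[i] for i in idx], pad_id)
            lengths = np.array([len(s) for s in xi])
            loss = _batch_loss(model, xb, yb, pad_id, rng, tf, sets[idx], lengths)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rows.append((start_epoch + epoch, float(np.mean(losses)), float("nan")))
    log = pd.concat(
        [trained.log, pd.DataFrame(rows, columns=["epoch", "train_loss", "val_token_acc"])],
        ignore_index=True,
    )
    return TrainedGenerator(model, config, log)


def save_generator(trained: TrainedGenerator, path) -> None:
    """Single-file pickle checkpoint (weights, vocabulary, config, log)."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(trained, fh)


def load_generator(path) -> TrainedGenerator:
    import pickle

    with open(path, "rb") as fh:
        trained = pickle.load(fh)
    if not isinstance(trained, TrainedGenerator):
        raise TypeError(f"{path} does not contain a generator checkpoint")
    return trained


def generate_description(model, contents: frozenset[str] | set[str]) -> str:
    """Greedy decoding of one sentence (with special tokens) from a content
    set; deterministic; hard stop at config.max_len tokens."""
    net = model.model if isinstance(model, TrainedGenerator) else model
    ids = np.array([_ids(net, encode_contents(contents))], dtype=np.int64)
    enc_states, h, c = net.encode(ids)
    enc_mask = np.zeros((1, ids.shape[1]), dtype=np.float32)
    set_vec = net.set_vector([contents])
    prev = np.array([net.stoi[SOS]])
    feed = net.init_feed(1)
    words = []
    for _ in range(net.config.max_len):
        logits, h, c, feed = net.decode_step(
            prev, h, c, enc_states, enc_mask, feed, set_vec
        )
        nxt = int(np.argmax(logits.data[0]))
        if net.vocab[nxt] == EOS:
            break
        words.append(net.vocab[nxt])
        prev = np.array([nxt])
    return " ".join(words)


def substitute_tokens(
    sentence: str, segment_name: str | None = None, size_mm: float | None = None
) -> str:
    """Replace ``<SEG>``/``<SIZE>`` with the actual values; any special token
    left without a value raises, listing it."""
    out = sentence
    if SEG_TOKEN in out:
        if segment_name is None:
            raise ValueError(f"no value provided for {SEG_TOKEN}")
        out = out.replace(SEG_TOKEN, segment_name)
    if SIZE_TOKEN in out:
        if size_mm is None:
            raise ValueError(f"no value provided for {SIZE_TOKEN}")
        size = f"{size_mm:g} mm"
        out = out.replace(SIZE_TOKEN, size)
    leftover = [t for t in (SEG_TOKEN, SIZE_TOKEN) if t in out]
    if leftover:
        raise ValueError(f"special tokens left in output: {leftover}")
    return out


def augment_corpus_iteration(
    model, unseen_combos, grammar: GrammarConfig
) -> tuple[list[tuple[frozenset[str], str]], list[dict]]:
    """Self-augmentation step: generate for unseen combinations, keep pairs
    passing adequacy (inversion == input) and fluency (grammar membership).

    Returns (accepted pairs, reject log)."""
    accepted, rejects = [], []
    for combo in unseen_combos:
        sentence = generate_description(model, combo)
        adequate = extract_contents(sentence, grammar) == frozenset(combo)
        fluent = is_grammatical(sentence, grammar)
        if adequate and fluent:
            accepted.append((frozenset(combo), sentence))
        else:
            rejects.append(
                {"combo": sorted(combo), "sentence": sentence,
                 "adequate": adequate, "fluent": fluent}
            )
    return accepted, rejects
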