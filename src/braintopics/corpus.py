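"""Meta-analytic corpora: documents pairing word tokens with activation peaks.

A corpus in this package mirrors the structure of coordinate-based
meta-analytic databases such as Neurosynth: each document (one published
study) carries (i) a bag of word tokens — unigram/bigram feature occurrences
drawn from the study abstract — and (ii) the study's reported peak-activation
coordinates in MNI millimetres.  Loading, vocabulary filtering, and a plain
JSON+TSV serialization bundle live here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BrainGrid

logger = logging.getLogger(__name__)


@dataclass
class Document:
    """One study: word-type token ids plus peak coordinates (MNI mm)."""

    doc_id: str
    word_tokens: np.ndarray  # (n_tokens,) int ids into the corpus vocabulary
    peaks: np.ndarray  # (n_peaks, 3) float mm

    def __post_init__(self):
        self.word_tokens = np.asarray(self.word_tokens, dtype=np.int64).reshape(-1)
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.peaks).all():
            raise ValueError(f"document {self.doc_id}: non-finite peak coordinates")


@dataclass
class Corpus:
    """A set of documents with a shared vocabulary and analysis grid."""

    documents: list
    vocabulary: list
    grid: BrainGrid
    _vocab_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._vocab_index = {w: i for i, w in enumerate(self.vocabulary)}
        W = len(self.vocabulary)
        for doc in self.documents:
            if doc.word_tokens.size and (
                doc.word_tokens.min() < 0 or doc.word_tokens.max() >= W
            ):
                raise ValueError(f"document {doc.doc_id}: token id outside vocabulary")

    def __len__(self):
        return len(self.documents)

    @property
    def n_word_types(self) -> int:
        return len(self.vocabulary)

    @property
    def n_word_tokens(self) -> int:
        return int(sum(d.word_tokens.size for d in self.documents))

    @property
    def n_peaks(self) -> int:
        return int(sum(len(d.peaks) for d in self.documents))

    def word_index(self, term: str) -> int:
        return self._vocab_index[term]

    # -- serialization: a JSON + TSV bundle --------------------------------
    #
    #   corpus.json        vocabulary, document ids/order, grid affine+shape
    #   coordinates.tsv    id, x, y, z          (one row per peak)
    #   word_tokens.tsv    id, term, count      (long features dialect)
    #   mask.nii.gz        the grid mask volume

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "braintopics-corpus-v1",
            "vocabulary": list(self.vocabulary),
            "doc_ids": [d.doc_id for d in self.documents],
            "grid": {
                "shape": list(self.grid.shape),
                "affine": self.grid.affine.tolist(),
            },
            "n_word_tokens": self.n_word_tokens,
            "n_peaks": self.n_peaks,
        }
        (directory / "corpus.json").write_text(json.dumps(meta, indent=1))
        coord_rows = []
        tok_rows = []
        for d in self.documents:
            for p in d.peaks:
                coord_rows.append((d.doc_id, p[0], p[1], p[2]))
            ids, counts = np.unique(d.word_tokens, return_counts=True)
            for i, n in zip(ids, counts):
                tok_rows.append((d.doc_id, self.vocabulary[i], int(n)))
        pd.DataFrame(coord_rows, columns=["id", "x", "y", "z"]).to_csv(
            directory / "coordinates.tsv", sep="\t", index=False
        )
        pd.DataFrame(tok_rows, columns=["id", "term", "count"]).to_csv(
            directory / "word_tokens.tsv", sep="\t", index=False
        )
        self.grid.to_mask_img().to_filename(str(directory / "mask.nii.gz"))

    @classmethod
    def load(cls, directory) -> "Corpus":
        directory = Path(directory)
        meta = json.loads((directory / "corpus.json").read_text())
        if meta.get("format") != "braintopics-corpus-v1":
            raise ValueError("not a braintopics corpus bundle")
        grid = BrainGrid.from_mask_img(directory / "mask.nii.gz")
        if list(grid.shape) != meta["grid"]["shape"]:
            raise ValueError("bundle mask does not match recorded grid shape")
        vocab = meta["vocabulary"]
        vocab_index = {w: i for i, w in enumerate(vocab)}
        coords = pd.read_csv(directory / "coordinates.tsv", sep="\t", dtype={"id": str})
        toks = pd.read_csv(directory / "word_tokens.tsv", sep="\t", dtype={"id": str})
        peaks_by_doc = {k: g[["x", "y", "z"]].to_numpy(float) for k, g in coords.groupby("id")}
        toks_by_doc = {k: g for k, g in toks.groupby("id")}
        docs = []
        for doc_id in meta["doc_ids"]:
            g = toks_by_doc.get(doc_id)
            tokens = []
            if g is not None:
                for term, n in zip(g["term"], g["count"]):
                    tokens.extend([vocab_index[term]] * int(n))
            docs.append(
                Document(
                    doc_id=doc_id,
                    word_tokens=np.array(tokens, dtype=np.int64),
                    peaks=peaks_by_doc.get(doc_id, np.empty((0, 3))),
                )
            )
        corpus = cls(documents=docs, vocabulary=vocab, grid=grid)
        if corpus.n_word_tokens != meta["n_word_tokens"] or corpus.n_peaks != meta["n_peaks"]:
            raise ValueError("bundle token/peak counts do not match recorded totals")
        return corpus


def _read_features(path) -> pd.DataFrame:
    """Read a features table, wide (doc x term) or long (id, term, count).

    The dialect is auto-detected from the header: a table whose first columns
    are ``id, term[, count]`` is long; anything else is treated as wide with
    the first column holding document ids and remaining columns term counts
    or occurrence flags.  Returns a long frame (id, term, count).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] == 0:
        raise ValueError("features table has no columns")
    cols = [c.lower() for c in df.columns]
    if cols[:2] == ["id", "term"] or cols[:2] == ["doc_id", "term"]:
        count_col = df.columns[2] if df.shape[1] > 2 else None
        out = pd.DataFrame(
            {
                "id": df.iloc[:, 0].astype(str),
                "term": df.iloc[:, 1].astype(str),
                "count": df[count_col] if count_col else 1,
            }
        )
    else:
        id_col = df.columns[0]
        out = df.melt(id_vars=[id_col], var_name="term", value_name="count")
        out = out.rename(columns={id_col: "id"})
        out["id"] = out["id"].astype(str)
    out["count"] = pd.to_numeric(out["count"], errors="raise").fillna(0)
    return out[out["count"] > 0]


def load_corpus(
    coordinates_table,
    features_table,
    grid: BrainGrid,
    min_doc_freq: int = 5,
) -> Corpus:
    """Build a :class:`Corpus` from coordinate and feature tables.

    Parameters
    ----------
    coordinates_table : path
        TSV with columns ``id, x, y, z`` (extra columns ignored); one row per
        reported activation peak.
    features_table : path
        TSV mapping documents to word-type counts or occurrence flags; wide
        or long dialect, auto-detected.
    grid : BrainGrid
        Analysis grid attached to the corpus.  Peaks are kept in continuous
        mm and are *not* snapped to the mask.
    min_doc_freq : int
        Word types occurring in fewer than this many documents are dropped.

    Documents appearing in only one of the two tables, and documents left
    with zero peaks or zero word tokens after filtering, are dropped with a
    logged warning: the generative model samples words conditional on a
    document's peak-topic counts, so a peak-free document has no defined word
    likelihood (and a word-free, peak-free pairing carries no signal).
    """
    coords = pd.read_csv(coordinates_table, sep="\t", dtype={"id": str})
    missing = {"id", "x", "y", "z"} - set(coords.columns)
    if missing:
        raise ValueError(f"coordinates table missing columns: {sorted(missing)}")
    feats = _read_features(features_table)

    coord_ids = list(dict.fromkeys(coords["id"]))  # first-appearance order
    feat_ids = set(feats["id"])
    shared = [i for i in coord_ids if i in feat_ids]
    for i in coord_ids:
        if i not in feat_ids:
            logger.warning("document %s has coordinates but no features; dropped", i)
    for i in sorted(feat_ids - set(coord_ids)):
        logger.warning("document %s has features but no coordinates; dropped", i)

    feats = feats[feats["id"].isin(shared)]
    doc_freq = feats.groupby("term")["id"].nunique()
    vocab = sorted(doc_freq.index[doc_freq >= min_doc_freq])
    vocab_index = {w: i for i, w in enumerate(vocab)}
    feats = feats[feats["term"].isin(vocab_index)]

    peaks_by_doc = {k: g[["x", "y", "z"]].to_numpy(float) for k, g in coords.groupby("id")}
    toks_by_doc = {k: g for k, g in feats.groupby("id")}

    docs = []
    for doc_id in shared:
        peaks = peaks_by_doc.get(doc_id, np.empty((0, 3)))
        g = toks_by_doc.get(doc_id)
        tokens = []
        if g is not None:
            for term, n in zip(g["term"], g["count"]):
                tokens.extend([vocab_index[term]] * int(round(float(n))))
        if len(peaks) == 0 or len(tokens) == 0:
            logger.warning(
                "document %s has %d peaks / %d word tokens after filtering; dropped",
                doc_id,
                len(peaks),
                len(tokens),
            )
            continue
        docs.append(Document(doc_id, np.array(tokens, dtype=np.int64), peaks))

    # restrict the vocabulary to types that actually survive in kept documents
    used = sorted({int(t) for d in docs for t in d.word_tokens})
    if len(used) != len(vocab):
        remap = {old: new for new, old in enumerate(used)}
        vocab = [vocab[i] for i in used]
        for d in docs:
            d.word_tokens = np.array([remap[int(t)] for t in d.word_tokens], dtype=np.int64)
    return Corpus(documents=docs, vocabulary=vocab, grid=grid)
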