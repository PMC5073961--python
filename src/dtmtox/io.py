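"""Readers and writers for the pipeline's on-disk formats.

Corpora use the LDA-C sparse format (one line per document:
``U id1:cnt1 id2:cnt2 ...``) with a ``-seq`` sidecar (number of slices,
then one document count per slice), a vocabulary file (one word per line,
line number = 0-based word id) and a document-metadata TSV.  Expression
studies are a genes x samples TSV plus a sample sheet.  All writes are
deterministic: identical inputs yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .corpus import Corpus, Document, ExpressionStudy, Vocabulary
from .interpret import GeneSetCollection

__all__ = [
    "read_ldac", "write_ldac", "read_corpus", "write_corpus",
    "read_expression", "write_expression", "read_gmt",
    "RunConfig", "write_fitted_model",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# -- LDA-C ----------------------------------------------------------------

def write_ldac(docs, path):
    """Write sparse documents (iterable of (word_ids, counts)) as LDA-C."""
    lines = []
    for ids, counts in docs:
        pairs = " ".join(f"{int(i)}:{int(c)}" for i, c in zip(ids, counts))
        n = len(ids)
        lines.append(f"{n} {pairs}" if n else "0")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ldac(path):
    """Parse an LDA-C file into a list of (word_ids, counts) arrays.

    The unique-word prefix of every line is validated against the number of
    pairs; malformed lines raise :class:`FormatError` citing the 1-based
    line number.
    """
    docs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        tokens = line.split()
        try:
            declared = int(tokens[0])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: bad unique-word count "
                              f"{tokens[0]!r}") from None
        pairs = tokens[1:]
        if len(pairs) != declared:
            raise FormatError(
                f"{path}, line {lineno}: declares {declared} unique words "
                f"but has {len(pairs)} pairs")
        ids = np.empty(declared, dtype=np.int64)
        cts = np.empty(declared, dtype=np.int64)
        for j, pair in enumerate(pairs):
            try:
                i, c = pair.split(":")
                ids[j], cts[j] = int(i), int(c)
            except ValueError:
                raise FormatError(f"{path}, line {lineno}: malformed pair "
                                  f"{pair!r}") from None
        if declared and (ids.min() < 0 or cts.min() < 1):
            raise FormatError(f"{path}, line {lineno}: ids must be >= 0 and "
                              f"counts >= 1")
        docs.append((ids, cts))
    return docs


# -- corpus bundle --------------------------------------------------------

def _paths(directory, stem):
    d = Path(directory)
    return (d / f"{stem}.ldac", d / f"{stem}-seq.dat", d / f"{stem}.vocab",
            d / f"{stem}.docs.tsv")


def write_corpus(corpus: Corpus, directory, stem="corpus"):
    """Write a corpus as LDA-C + seq sidecar + vocabulary + doc metadata."""
    ldac, seq, vocab, docmeta = _paths(directory, stem)
    Path(directory).mkdir(parents=True, exist_ok=True)
    write_ldac(((d.word_ids, d.counts) for d in corpus.documents), ldac)
    sizes = corpus.slice_sizes
    seq.write_text("\n".join([str(len(sizes))] + [str(s) for s in sizes]) + "\n")
    vocab.write_text("\n".join(corpus.vocabulary.words) + "\n")
    meta = pd.DataFrame(
        [(d.doc_id, d.compound_id, d.time_point) for d in corpus.documents],
        columns=["doc_id", "compound_id", "time_point"],
    )
    meta.to_csv(docmeta, sep="\t", index=False)
    return ldac, seq, vocab, docmeta


def _vocabulary_from_words(words):
    if len(words) % 2:
        raise FormatError("vocabulary length must be even (up/down pairs)")
    genes = []
    for i in range(0, len(words), 2):
        up, down = words[i], words[i + 1]
        if not (up.endswith("_up") and down.endswith("_down")
                and up[:-3] == down[:-5]):
            raise FormatError(f"vocabulary lines {i + 1}-{i + 2}: expected "
                              f"<gene>_up / <gene>_down, got {up!r}, {down!r}")
        genes.append(up[:-3])
    return Vocabulary(genes)


def read_corpus(directory, stem="corpus") -> Corpus:
    """Read back a corpus bundle written by :func:`write_corpus`."""
    ldac, seq, vocab, docmeta = _paths(directory, stem)
    docs_sparse = read_ldac(ldac)
    seq_lines = [int(x) for x in seq.read_text().split()]
    n_slices, sizes = seq_lines[0], seq_lines[1:]
    if len(sizes) != n_slices:
        raise FormatError(f"{seq}: header declares {n_slices} slices but "
                          f"{len(sizes)} counts follow")
    if sum(sizes) != len(docs_sparse):
        raise FormatError(f"{seq}: slice sizes sum to {sum(sizes)} but the "
                          f"corpus has {len(docs_sparse)} documents")
    vocabulary = _vocabulary_from_words(vocab.read_text().splitlines())
    meta = pd.read_csv(docmeta, sep="\t")
    slice_of_doc = np.repeat(np.arange(n_slices), sizes)
    documents = []
    time_labels = [None] * n_slices
    for j, (ids, cts) in enumerate(docs_sparse):
        s = int(slice_of_doc[j])
        row = meta.iloc[j]
        time_labels[s] = row["time_point"]
        documents.append(Document(
            doc_id=row["doc_id"], compound_id=row["compound_id"],
            time_point=row["time_point"], slice_index=s,
            word_ids=ids, counts=cts,
        ))
    if any(t is None for t in time_labels):
        time_labels = list(range(n_slices))
    return Corpus(vocabulary=vocabulary, documents=documents,
                  time_labels=time_labels)


# -- expression studies ---------------------------------------------------

def read_expression(matrix_path, meta_path) -> ExpressionStudy:
    """Load a genes x samples log2 TSV and its sample sheet."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    return ExpressionStudy(values=values, sample_meta=meta)


def write_expression(study: ExpressionStudy, matrix_path, meta_path):
    study.values.to_csv(matrix_path, sep="\t", index_label="gene_id",
                        float_format="%.6g")
    study.sample_meta.reset_index().rename(columns={"index": "sample_id"}) \
        .to_csv(meta_path, sep="\t", index=False)


# -- gene sets ------------------------------------------------------------

def read_gmt(path, source="") -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members per line)."""
    return GeneSetCollection(_gseapy_read_gmt(str(path)), source=source)


# -- run configuration ----------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Fully resolved pipeline configuration, serialized alongside outputs."""

    n_topics: int = 20
    alpha: float = 0.01
    chain_variance: float = 0.005
    init_variance: float = None
    obs_variance: float = 0.005
    em_max_iter: int = 50
    em_rel_tol: float = 1e-4
    doc_max_iter: int = 100
    doc_tol: float = 1e-3
    m_step_iter: int = 15
    deg_threshold: float = 1.0
    count_scale: float = 100.0
    top_n: int = 300
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def model_kwargs(self) -> dict:
        return dict(
            n_topics=self.n_topics, alpha=self.alpha,
            chain_variance=self.chain_variance,
            init_variance=self.init_variance, obs_variance=self.obs_variance,
            em_max_iter=self.em_max_iter, em_rel_tol=self.em_rel_tol,
            doc_max_iter=self.doc_max_iter, doc_tol=self.doc_tol,
            m_step_iter=self.m_step_iter, random_state=self.seed,
        )


# -- fitted model bundle --------------------------------------------------

def write_fitted_model(model, directory, config: RunConfig = None):
    """Write doc-topic / per-slice topic-word TSVs, the ELBO trace and a
    JSON manifest (config, convergence) into one directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    topics = [f"topic_{k}" for k in range(model.doc_topic_.shape[1])]
    words = model.vocabulary_.words
    pd.DataFrame(model.doc_topic_, index=model.doc_ids_, columns=topics) \
        .to_csv(d / "doc_topic.tsv", sep="\t", index_label="doc_id")
    for t, label in enumerate(model.time_labels_):
        pd.DataFrame(model.topic_word_[t], index=topics, columns=words) \
            .to_csv(d / f"topic_word_slice{t}.tsv", sep="\t",
                    index_label=f"time_{label}")
    pd.DataFrame({"iteration": np.arange(len(model.elbo_trace_)),
                  "elbo": model.elbo_trace_}) \
        .to_csv(d / "elbo_trace.tsv", sep="\t", index=False)
    manifest = {
        "converged": bool(model.converged_),
        "n_iter": int(model.n_iter_),
        "n_topics": int(model.doc_topic_.shape[1]),
        "n_slices": len(model.time_labels_),
        "time_labels": [str(x) for x in model.time_labels_],
        "config": json.loads(config.to_json()) if config else None,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return d


class FittedModelView:
    """Read-only view of a written model bundle, sufficient for
    interpretation (doc_topic_, topic_word_, vocabulary, labels)."""

    def __init__(self, doc_topic_, topic_word_, doc_ids_, time_labels_,
                 vocabulary_, manifest):
        self.doc_topic_ = doc_topic_
        self.topic_word_ = topic_word_
        self.doc_ids_ = doc_ids_
        self.time_labels_ = time_labels_
        self.vocabulary_ = vocabulary_
        self.manifest = manifest


def read_fitted_model(directory) -> FittedModelView:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    dt = pd.read_csv(d / "doc_topic.tsv", sep="\t", index_col=0)
    slices = []
    words = None
    for t in range(manifest["n_slices"]):
        tw = pd.read_csv(d / f"topic_word_slice{t}.tsv", sep="\t", index_col=0)
        words = list(tw.columns)
        slices.append(tw.to_numpy())
    return FittedModelView(
        doc_topic_=dt.to_numpy(),
        topic_word_=np.stack(slices, axis=0),
        doc_ids_=list(dt.index),
        time_labels_=manifest["time_labels"],
        vocabulary_=_vocabulary_from_words(words),
        manifest=manifest,
    )
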