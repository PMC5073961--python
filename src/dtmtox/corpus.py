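"""Turn expression studies into time-sliced bag-of-DEG-words corpora.

A *document* is one compound at one time point; its *words* are the
differentially expressed genes of the treated-vs-matched-control contrast,
split by transcriptional direction (``Acot1_up``, ``Stac3_down``).  The
word count encodes effect size: ``round(100 * fold_change)``, where the
fold change is the direction-normalized linear ratio (always >= 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOSE_CONTROL = "control"
DOSE_TREATED = "treated"

META_COLUMNS = ("compound_id", "time_point", "dose_group", "replicate")


class ContrastUnavailableError(ValueError):
    """A (compound, time) cell is missing one of the two dose groups."""

    def __init__(self, compound, time_point, missing):
        self.compound = compound
        self.time_point = time_point
        super().__init__(
            f"no {missing!r} samples for compound {compound!r} "
            f"at time point {time_point!r}"
        )


@dataclass
class ExpressionStudy:
    """Gene-level log2 intensity matrix plus per-sample design metadata.

    Parameters
    ----------
    values : DataFrame, genes x samples
        log2 intensities; the index holds unique gene identifiers.
    sample_meta : DataFrame indexed by sample id
        Columns ``compound_id``, ``time_point``, ``dose_group``
        (``control`` / ``treated``) and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing_cols = set(META_COLUMNS) - set(self.sample_meta.columns)
        if missing_cols:
            raise ValueError(f"sample sheet lacks columns {sorted(missing_cols)}")
        unknown = set(self.sample_meta.index) - set(self.values.columns)
        if unknown:
            raise ValueError(f"samples in sheet but not in matrix: {sorted(unknown)[:5]}")
        bad_dose = set(self.sample_meta["dose_group"]) - {DOSE_CONTROL, DOSE_TREATED}
        if bad_dose:
            raise ValueError(f"unknown dose groups {sorted(bad_dose)}")
        # column order of values follows the sample sheet
        self.values = self.values[self.sample_meta.index]

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def time_points(self) -> list:
        """Strictly ordered time points present in the design."""
        return sorted(self.sample_meta["time_point"].unique())

    @property
    def compounds(self) -> list:
        return sorted(self.sample_meta["compound_id"].unique())

    def samples_for(self, compound, time_point, dose_group) -> list:
        m = self.sample_meta
        sel = (
            (m["compound_id"] == compound)
            & (m["time_point"] == time_point)
            & (m["dose_group"] == dose_group)
        )
        return list(m.index[sel])


class Vocabulary:
    """Bijection between word ids and (gene, direction) pairs.

    Words are ordered ``g1_up, g1_down, g2_up, g2_down, ...`` following the
    input gene order, so the vocabulary has exactly ``2 * n_genes`` entries.
    """

    DIRECTIONS = ("up", "down")

    def __init__(self, gene_ids):
        gene_ids = list(gene_ids)
        seen = set()
        for g in gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r}")
            seen.add(g)
        self.gene_ids = gene_ids
        self.words = [f"{g}_{d}" for g in gene_ids for d in self.DIRECTIONS]
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    def __len__(self):
        return len(self.words)

    def encode(self, gene_id, direction) -> int:
        if direction not in self.DIRECTIONS:
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        try:
            gi = self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in vocabulary") from None
        return 2 * gi + self.DIRECTIONS.index(direction)

    def decode(self, word_id) -> tuple:
        gene = self.gene_ids[word_id // 2]
        return gene, self.DIRECTIONS[word_id % 2]

    def word(self, word_id) -> str:
        return self.words[word_id]


def build_vocabulary(gene_ids) -> Vocabulary:
    """Direction-split vocabulary over a gene universe (2 words per gene)."""
    return Vocabulary(gene_ids)


@dataclass
class Document:
    """One compound-time condition as a sparse bag of direction-split words."""

    doc_id: str
    compound_id: object
    time_point: object
    slice_index: int
    word_ids: np.ndarray  # int array, sorted ascending
    counts: np.ndarray  # positive int array, aligned with word_ids

    def __post_init__(self):
        self.word_ids = np.asarray(self.word_ids, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 1):
            raise ValueError(f"document {self.doc_id}: counts must be >= 1")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return dict(zip(self.word_ids.tolist(), self.counts.tolist()))


@dataclass
class Corpus:
    """Slice-major ordered documents over a shared vocabulary."""

    vocabulary: Vocabulary
    documents: list
    time_labels: list = field(default_factory=list)

    def __post_init__(self):
        slices = [d.slice_index for d in self.documents]
        if slices != sorted(slices):
            raise ValueError("documents must be ordered slice-major")
        if not self.time_labels and self.documents:
            self.time_labels = list(range(max(slices) + 1))

    @property
    def n_slices(self) -> int:
        return len(self.time_labels)

    @property
    def slice_sizes(self) -> list:
        sizes = [0] * self.n_slices
        for d in self.documents:
            sizes[d.slice_index] += 1
        return sizes

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    def __len__(self):
        return len(self.documents)

    def total_tokens(self) -> int:
        return sum(d.total for d in self.documents)


def compute_fold_changes(study: ExpressionStudy, compound, time_point) -> pd.DataFrame:
    """Treated-vs-matched-control contrast for one compound-time cell.

    Replicates are averaged in log2 space; the fold change is
    ``2 ** |mean(treated) - mean(control)|`` (linear, direction-normalized,
    hence >= 1) and the direction is ``up`` iff the difference is >= 0.

    Returns a DataFrame with one row per gene: ``gene_id``, ``compound_id``,
    ``time_point``, ``log2_diff`` (signed), ``fold_change``, ``direction``,
    ``is_deg`` (initialized False; see :func:`select_degs`).
    """
    treated = study.samples_for(compound, time_point, DOSE_TREATED)
    control = study.samples_for(compound, time_point, DOSE_CONTROL)
    if not treated:
        raise ContrastUnavailableError(compound, time_point, DOSE_TREATED)
    if not control:
        raise ContrastUnavailableError(compound, time_point, DOSE_CONTROL)
    diff = study.values[treated].mean(axis=1) - study.values[control].mean(axis=1)
    diff = diff.to_numpy()
    return pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "compound_id": compound,
            "time_point": time_point,
            "log2_diff": diff,
            "fold_change": np.exp2(np.abs(diff)),
            "direction": np.where(diff >= 0, "up", "down"),
            "is_deg": False,
        }
    )


def select_degs(records: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Flag differentially expressed genes at an absolute log2-fold-change cutoff."""
    if threshold < 0:
        raise ValueError(f"DEG threshold must be >= 0, got {threshold}")
    out = records.copy()
    out["is_deg"] = np.abs(out["log2_diff"].to_numpy()) >= threshold
    return out


def _count_from_fold_change(fc: np.ndarray, scale: float, cap) -> np.ndarray:
    if np.any(fc < 1):
        raise AssertionError("internal invariant violated: fold_change < 1")
    # round half away from zero (values are positive), floored at 1
    counts = np.floor(scale * fc + 0.5).astype(np.int64)
    counts = np.maximum(counts, 1)
    if cap is not None:
        counts = np.minimum(counts, int(cap))
    return counts


def encode_documents(
    deg_records: pd.DataFrame,
    vocabulary: Vocabulary,
    time_order,
    count_scale: float = 100.0,
    count_cap=None,
) -> Corpus:
    """Encode flagged DEG records into a slice-major corpus.

    ``deg_records`` holds the concatenated output of :func:`select_degs` for
    every (compound, time) contrast to include; rows with ``is_deg`` False
    are dropped.  Word counts are ``round(count_scale * fold_change)``
    floored at 1.  Compound-time groups with no DEGs become empty documents
    and are flagged in the log.
    """
    time_order = list(time_order)
    slice_of = {t: i for i, t in enumerate(time_order)}
    unknown_t = set(deg_records["time_point"]) - set(slice_of)
    if unknown_t:
        raise ValueError(f"time points outside declared order: {sorted(unknown_t)}")

    docs = []
    groups = deg_records.groupby(["compound_id", "time_point"], sort=True)
    for (compound, tp), grp in groups:
        grp = grp[grp["is_deg"]]
        word_ids = np.array(
            [vocabulary.encode(g, d) for g, d in zip(grp["gene_id"], grp["direction"])],
            dtype=np.int64,
        )
        if word_ids.size == 0:
            logger.warning("empty document: compound %r at time %r has no DEGs", compound, tp)
            counts = np.array([], dtype=np.int64)
        else:
            counts = _count_from_fold_change(
                grp["fold_change"].to_numpy(), count_scale, count_cap
            )
            order = np.argsort(word_ids)
            word_ids, counts = word_ids[order], counts[order]
        docs.append(
            Document(
                doc_id=f"{compound}@{tp}",
                compound_id=compound,
                time_point=tp,
                slice_index=slice_of[tp],
                word_ids=word_ids,
                counts=counts,
            )
        )
    docs.sort(key=lambda d: (d.slice_index, str(d.compound_id)))
    return Corpus(vocabulary=vocabulary, documents=docs, time_labels=time_order)


class CorpusBuilder:
    """End-to-end study -> corpus pipeline with the standard defaults.

    Parameters
    ----------
    deg_threshold : float
        Absolute log2 fold-change cutoff for DEG calling (default 1.0,
        i.e. two-fold).
    count_scale : float
        Multiplier mapping fold change to word count (default 100).
    count_cap : int or None
        Optional ceiling on word counts.
    keep_partial : bool
        Keep compounds that lack some time points (default False: such
        compounds are dropped entirely, with a warning).
    """

    def __init__(self, deg_threshold=1.0, count_scale=100.0, count_cap=None,
                 keep_partial=False):
        self.deg_threshold = deg_threshold
        self.count_scale = count_scale
        self.count_cap = count_cap
        self.keep_partial = keep_partial

    def build(self, study: ExpressionStudy) -> Corpus:
        time_order = study.time_points
        vocab = build_vocabulary(study.gene_ids)
        tables = []
        for compound in study.compounds:
            per_time = []
            try:
                for tp in time_order:
                    fc = compute_fold_changes(study, compound, tp)
                    per_time.append(select_degs(fc, self.deg_threshold))
            except ContrastUnavailableError as err:
                if self.keep_partial:
                    logger.warning("keeping partial compound %r: %s", compound, err)
                else:
                    logger.warning("dropping compound %r: %s", compound, err)
                    continue
            tables.extend(per_time)
        if not tables:
            raise ValueError("no complete compound contrasts; corpus would be empty")
        records = pd.concat(tables, ignore_index=True)
        return encode_documents(
            records, vocab, time_order,
            count_scale=self.count_scale, count_cap=self.count_cap,
        )
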