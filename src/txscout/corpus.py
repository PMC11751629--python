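"""Corpus I/O: ARCHS4-style HDF5 count matrices, GMT gene sets, embedding databases.

An ARCHS4-style corpus is an HDF5 file holding a genes x samples count matrix
plus per-sample metadata (accession, series, title, source, characteristics)
and per-study text (title, summary, overall design). Dataset paths are not
hard-coded: an :class:`H5Layout` maps logical fields to HDF5 paths so that
layout drift between corpus versions stays configurable. Gene identity is by
symbol string, case-sensitive.

Embedding databases (one vector per study, or per study x condition) persist
as a raw ``.npy`` array next to a JSON sidecar carrying ids and provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "ARCHS4_V2_LAYOUT",
    "Corpus",
    "CorpusFormatError",
    "EmbeddingDB",
    "EmbeddingDBError",
    "GeneSet",
    "GmtParseError",
    "H5Layout",
    "SampleRecord",
    "StudyRecord",
    "assemble_study_text",
    "load_embedding_db",
    "read_archs4_h5",
    "read_gmt",
    "save_embedding_db",
    "write_corpus",
    "write_gmt",
]

EMBEDDING_DB_VERSION = 1


class CorpusFormatError(ValueError):
    """Raised when an HDF5 corpus file violates the expected layout."""


class GmtParseError(ValueError):
    """Raised on malformed GMT gene-set lines."""


class EmbeddingDBError(ValueError):
    """Raised when a persisted embedding database cannot be loaded intact."""


@dataclass(frozen=True)
class SampleRecord:
    """One assay (GEO GSM-style sample) of a study."""

    sample_id: str
    study_id: str
    condition_label: str = ""
    sample_text: str = ""
    source_name: str = ""


@dataclass(frozen=True)
class StudyRecord:
    """One study (GEO GSE-style series) with its descriptive text."""

    study_id: str
    title: str = ""
    summary: str = ""
    overall_design: str = ""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a free-text description."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")


@dataclass
class Corpus:
    """In-memory corpus: counts (genes x samples) plus sample/study metadata."""

    counts: np.ndarray
    gene_ids: list[str]
    samples: list[SampleRecord]
    studies: list[StudyRecord]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise CorpusFormatError("counts must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise CorpusFormatError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_samples != len(self.samples):
            raise CorpusFormatError(
                f"counts has {n_samples} columns but {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CorpusFormatError("gene ids are not unique")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise CorpusFormatError("sample ids are not unique")
        study_ids = [s.study_id for s in self.studies]
        if len(set(study_ids)) != len(study_ids):
            raise CorpusFormatError("study ids are not unique")
        known = set(study_ids)
        for s in self.samples:
            if s.study_id not in known:
                raise CorpusFormatError(
                    f"sample {s.sample_id} references unknown study {s.study_id}"
                )
        if self.counts.size and self.counts.min() < 0:
            raise CorpusFormatError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def samples_of_study(self, study_id: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.study_id == study_id]

    def study_sample_ids(self) -> dict[str, list[str]]:
        """Map study_id -> sample ids in stored sample order."""
        out: dict[str, list[str]] = {s.study_id: [] for s in self.studies}
        for s in self.samples:
            out[s.study_id].append(s.sample_id)
        return out

    def sample_index(self) -> dict[str, int]:
        return {s.sample_id: i for i, s in enumerate(self.samples)}


@dataclass(frozen=True)
class H5Layout:
    """Logical field -> HDF5 dataset path map for a corpus file.

    Defaults mirror ARCHS4 v2 naming for the expression matrix and per-sample
    fields; per-study text lives under ``meta/series``. Missing optional text
    datasets are read as empty strings.
    """

    counts: str = "data/expression"
    gene_symbols: str = "meta/genes/symbol"
    sample_accession: str = "meta/samples/geo_accession"
    sample_series: str = "meta/samples/series_id"
    sample_title: str = "meta/samples/title"
    sample_source: str = "meta/samples/source_name_ch1"
    sample_characteristics: str = "meta/samples/characteristics_ch1"
    sample_condition: str = "meta/samples/condition"
    study_accession: str = "meta/series/series_id"
    study_title: str = "meta/series/title"
    study_summary: str = "meta/series/summary"
    study_design: str = "meta/series/overall_design"


ARCHS4_V2_LAYOUT = H5Layout()


def _read_strings(f: h5py.File, path: str, n: int, *, required: bool) -> list[str]:
    if path not in f:
        if required:
            raise CorpusFormatError(f"corpus file is missing dataset {path!r}")
        return [""] * n
    data = f[path].asstr()[...]
    if data.shape[0] != n:
        raise CorpusFormatError(
            f"dataset {path!r} has length {data.shape[0]}, expected {n}"
        )
    return [str(x) for x in data]


def read_archs4_h5(path: str | Path, layout: H5Layout = ARCHS4_V2_LAYOUT) -> Corpus:
    """Read an ARCHS4-style HDF5 corpus file.

    Parameters
    ----------
    path:
        HDF5 file to read.
    layout:
        Dataset-path map; defaults to the ARCHS4 v2 dialect.

    Raises
    ------
    CorpusFormatError
        If a required dataset is absent or dimensions are inconsistent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with h5py.File(path, "r") as f:
        if layout.counts not in f:
            raise CorpusFormatError(f"corpus file is missing dataset {layout.counts!r}")
        counts = np.asarray(f[layout.counts][...])
        if counts.ndim != 2:
            raise CorpusFormatError(f"dataset {layout.counts!r} is not 2-D")
        n_genes, n_samples = counts.shape
        gene_ids = _read_strings(f, layout.gene_symbols, n_genes, required=True)
        accession = _read_strings(f, layout.sample_accession, n_samples, required=True)
        series = _read_strings(f, layout.sample_series, n_samples, required=True)
        titles = _read_strings(f, layout.sample_title, n_samples, required=False)
        sources = _read_strings(f, layout.sample_source, n_samples, required=False)
        chars = _read_strings(f, layout.sample_characteristics, n_samples, required=False)
        conditions = _read_strings(f, layout.sample_condition, n_samples, required=False)

        samples = []
        for i in range(n_samples):
            text = " ".join(t for t in (titles[i], sources[i], chars[i]) if t)
            samples.append(
                SampleRecord(
                    sample_id=accession[i],
                    study_id=series[i],
                    condition_label=conditions[i],
                    sample_text=text,
                    source_name=sources[i],
                )
            )

        if layout.study_accession in f:
            n_studies = f[layout.study_accession].shape[0]
            study_ids = _read_strings(f, layout.study_accession, n_studies, required=True)
            s_titles = _read_strings(f, layout.study_title, n_studies, required=False)
            s_summaries = _read_strings(f, layout.study_summary, n_studies, required=False)
            s_designs = _read_strings(f, layout.study_design, n_studies, required=False)
            studies = [
                StudyRecord(study_ids[i], s_titles[i], s_summaries[i], s_designs[i])
                for i in range(n_studies)
            ]
        else:
            studies = []

        # Any series referenced by a sample but absent from the study table
        # becomes a text-less study so the corpus invariants hold.
        known = {s.study_id for s in studies}
        extra = [sid for sid in dict.fromkeys(series) if sid not in known]
        if extra and studies:
            warnings.warn(
                f"{len(extra)} series missing from the study table; added without text",
                stacklevel=2,
            )
        studies.extend(StudyRecord(sid) for sid in extra)

    return Corpus(counts=counts, gene_ids=gene_ids, samples=samples, studies=studies)


def write_corpus(
    corpus: Corpus, path: str | Path, layout: H5Layout = ARCHS4_V2_LAYOUT
) -> Path:
    """Write a corpus to HDF5 in the given layout (inverse of read_archs4_h5)."""
    path = Path(path)
    str_dt = h5py.string_dtype(encoding="utf-8")

    def put(f: h5py.File, dset: str, values: Sequence[str]) -> None:
        f.create_dataset(dset, data=np.asarray(values, dtype=object), dtype=str_dt)

    with h5py.File(path, "w") as f:
        f.create_dataset(layout.counts, data=np.asarray(corpus.counts))
        put(f, layout.gene_symbols, corpus.gene_ids)
        put(f, layout.sample_accession, [s.sample_id for s in corpus.samples])
        put(f, layout.sample_series, [s.study_id for s in corpus.samples])
        put(f, layout.sample_title, [s.sample_text for s in corpus.samples])
        put(f, layout.sample_source, [s.source_name for s in corpus.samples])
        put(f, layout.sample_characteristics, ["" for _ in corpus.samples])
        put(f, layout.sample_condition, [s.condition_label for s in corpus.samples])
        put(f, layout.study_accession, [s.study_id for s in corpus.studies])
        put(f, layout.study_title, [s.title for s in corpus.studies])
        put(f, layout.study_summary, [s.summary for s in corpus.studies])
        put(f, layout.study_design, [s.overall_design for s in corpus.studies])
    return path


def assemble_study_text(study: StudyRecord) -> str:
    """Concatenate title, summary and overall design, skipping empty fields."""
    return " ".join(t for t in (study.title, study.summary, study.overall_design) if t)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (one tab-separated gene set per line).

    Each non-empty line must have at least three fields: name, description and
    one gene. Duplicate symbols within a line are collapsed.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"line {lineno}: expected name, description and >=1 gene, "
                    f"got {len(fields)} field(s)"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GmtParseError(f"line {lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=description, genes=genes))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> Path:
    """Serialize gene sets to GMT, genes sorted for reproducibility."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")
    return path


@dataclass
class EmbeddingDB:
    """Ordered ids plus an (n x d) matrix of embedding vectors with provenance."""

    ids: list[str]
    vectors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise EmbeddingDBError("vectors must be a 2-D matrix")
        if self.vectors.shape[0] != len(self.ids):
            raise EmbeddingDBError(
                f"{self.vectors.shape[0]} vector rows for {len(self.ids)} ids"
            )
        if len(set(self.ids)) != len(self.ids):
            raise EmbeddingDBError("embedding ids are not unique")
        if self.vectors.size and not np.all(np.isfinite(self.vectors)):
            raise EmbeddingDBError("embedding vectors contain non-finite values")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def vector_for(self, id_: str) -> np.ndarray:
        return self.vectors[self._index[id_]]


def _db_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".npy", ".json"}:
        base = base.with_suffix("")
    return base.with_suffix(".npy"), base.with_suffix(".json")


def save_embedding_db(db: EmbeddingDB, path: str | Path) -> tuple[Path, Path]:
    """Persist *db* as ``<path>.npy`` (vectors) + ``<path>.json`` (ids, meta)."""
    npy, sidecar = _db_paths(path)
    np.save(npy, db.vectors)
    payload = {"version": EMBEDDING_DB_VERSION, "ids": db.ids, "meta": db.meta}
    sidecar.write_text(json.dumps(payload, sort_keys=True))
    return npy, sidecar


def load_embedding_db(path: str | Path) -> EmbeddingDB:
    """Load an embedding database written by :func:`save_embedding_db`."""
    npy, sidecar = _db_paths(path)
    if not npy.exists() or not sidecar.exists():
        raise EmbeddingDBError(f"embedding database incomplete at {npy.with_suffix('')}")
    try:
        payload = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise EmbeddingDBError(f"corrupt sidecar {sidecar}: {exc}") from exc
    if payload.get("version") != EMBEDDING_DB_VERSION:
        raise EmbeddingDBError(
            f"unsupported embedding DB version {payload.get('version')!r}"
        )
    try:
        vectors = np.load(npy)
    except (ValueError, EOFError) as exc:
        raise EmbeddingDBError(f"corrupt vector file {npy}: {exc}") from exc
    return EmbeddingDB(ids=list(payload["ids"]), vectors=vectors, meta=payload["meta"])
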