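"""Reproducible synthetic SRA submissions for testing and demos.

The generator mints an internally consistent accession graph (submissions →
studies → experiments → runs, experiments → samples) and fills free-text
fields from a small biomedical vocabulary, so that every other module can be
exercised without downloading anything.  Phrases can be planted verbatim in
chosen fields (for search tests) and whole records can be embedded unmodified.
The same seed always yields byte-identical XML.

The generated content is deliberately simple: accessions are sequential,
vocabulary is a few dozen words, and field lengths are short.  It emulates
the *structure* of real submissions (linked objects, multi-valued attributes,
controlled vocabularies), not the statistical texture of real SRA content.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

from . import metastore, sra_xml
from .sra_xml import (ExperimentRecord, RunRecord, SampleRecord, StudyRecord,
                      SubmissionRecord, record_kind, write_object_set)

DEFAULT_VOCABULARY = tuple(
    "breast cancer Carcinoma tumor genome transcriptome sequencing expression "
    "cell line tissue blood liver lung brain kidney human mouse profiling "
    "analysis methylation chromatin binding variant exome control treated "
    "resistant ductal primary metastatic clinical cohort replicate library "
    "illumina polyA enrichment capture signaling pathway receptor".split())

LIBRARY_STRATEGIES = ("WGS", "WXS", "RNA-Seq", "AMPLICON", "OTHER", "ChIP-Seq")
LIBRARY_SOURCES = ("GENOMIC", "TRANSCRIPTOMIC", "METAGENOMIC", "OTHER")
LIBRARY_SELECTIONS = ("RANDOM", "PCR", "cDNA", "other")
PLATFORMS = (("ILLUMINA", "Illumina Genome Analyzer II"),
             ("ILLUMINA", "Illumina HiSeq 2000"),
             ("LS454", "454 GS FLX"),
             ("ABI_SOLID", "AB SOLiD System 3.0"))
STUDY_TYPES = ("Transcriptome Analysis", "Whole Genome Sequencing",
               "Epigenetics", "Other")


@dataclass
class SynthSpec:
    """Parameters of one synthetic submission set."""
    seed: int = 0
    n_studies: int = 3
    experiments_per_study: Tuple[int, int] = (1, 3)
    runs_per_experiment: Tuple[int, int] = (1, 3)
    attribute_count: Tuple[int, int] = (0, 3)
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY
    planted_phrases: List[Tuple[str, str, str]] = dc_field(default_factory=list)
    planted_records: List[object] = dc_field(default_factory=list)
    prefix: str = "S"  # archive letter: S (NCBI), E (EBI) or D (DDBJ)

    def validate(self):
        for lo, hi in (self.experiments_per_study, self.runs_per_experiment,
                       self.attribute_count):
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range ({lo}, {hi})")
        if self.n_studies < 0:
            raise ValueError("n_studies must be >= 0")
        if self.prefix not in ("S", "E", "D"):
            raise ValueError(f"prefix must be S, E or D, got {self.prefix!r}")
        for record in self.planted_records:
            record_kind(record)  # raises for non-records
        for kind, field_name, _ in self.planted_phrases:
            if kind not in sra_xml.KINDS:
                raise ValueError(f"planted phrase names unknown kind {kind!r}")
            if field_name not in sra_xml.record_fields(kind):
                raise ValueError(
                    f"planted phrase names unknown field {kind}.{field_name}")


class _Minter:
    """Sequential, collision-free accession minting per entity kind."""

    _LETTER = {"submission": "A", "study": "P", "sample": "S",
               "experiment": "X", "run": "R"}

    def __init__(self, prefix: str):
        self.prefix = prefix
        self.counters = {kind: 0 for kind in sra_xml.KINDS}

    def mint(self, kind: str) -> str:
        self.counters[kind] += 1
        return f"{self.prefix}R{self._LETTER[kind]}{self.counters[kind]:06d}"


def _words(rng: random.Random, vocab, lo=3, hi=8) -> str:
    return " ".join(rng.choice(vocab) for _ in range(rng.randint(lo, hi)))


def _attrs(rng: random.Random, spec: SynthSpec) -> Optional[str]:
    n = rng.randint(*spec.attribute_count)
    pairs = [(rng.choice(spec.vocabulary), _words(rng, spec.vocabulary, 1, 3))
             for _ in range(n)]
    return sra_xml.flatten_multivalue(pairs)


def _date(rng: random.Random) -> str:
    return f"{rng.randint(2008, 2012)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"


def generate_records(spec: SynthSpec) -> Dict[str, list]:
    """Generate the internal record graph for ``spec`` (kind -> records)."""
    spec.validate()
    rng = random.Random(spec.seed)
    minter = _Minter(spec.prefix)
    vocab = list(spec.vocabulary)
    records: Dict[str, list] = {kind: [] for kind in sra_xml.KINDS}

    n_submissions = max(1, spec.n_studies // 2) if spec.n_studies else 1
    submissions = []
    for _ in range(n_submissions):
        acc = minter.mint("submission")
        records["submission"].append(SubmissionRecord(
            submission_accession=acc,
            submission_alias=f"sub_{acc}",
            center_name=rng.choice(("NCI", "WUGSC", "BI", "KUGSPS")),
            submission_date=_date(rng),
            submission_attribute=_attrs(rng, spec),
        ))
        submissions.append(acc)

    for s in range(spec.n_studies):
        sub_acc = submissions[s % n_submissions]
        study_acc = minter.mint("study")
        records["study"].append(StudyRecord(
            study_accession=study_acc,
            study_alias=f"study_{study_acc}",
            study_title=_words(rng, vocab, 3, 6),
            study_type=rng.choice(STUDY_TYPES),
            study_abstract=_words(rng, vocab, 8, 20),
            center_name=rng.choice(("NCI", "WUGSC", "BI", "KUGSPS")),
            study_description=_words(rng, vocab, 5, 12),
            study_attribute=_attrs(rng, spec),
            submission_accession=sub_acc,
        ))
        for _ in range(rng.randint(*spec.experiments_per_study)):
            sample_acc = minter.mint("sample")
            records["sample"].append(SampleRecord(
                sample_accession=sample_acc,
                sample_alias=f"sample_{sample_acc}",
                taxon_id=rng.choice((9606, 10090, 562)),
                scientific_name=rng.choice(
                    ("Homo sapiens", "Mus musculus", "Escherichia coli")),
                description=_words(rng, vocab, 3, 8),
                sample_attribute=_attrs(rng, spec),
                submission_accession=sub_acc,
            ))
            exp_acc = minter.mint("experiment")
            platform, model = rng.choice(PLATFORMS)
            records["experiment"].append(ExperimentRecord(
                experiment_accession=exp_acc,
                experiment_alias=f"exp_{exp_acc}",
                title=_words(rng, vocab, 3, 6),
                study_accession=study_acc,
                sample_accession=sample_acc,
                design_description=_words(rng, vocab, 4, 10),
                library_name=f"lib_{exp_acc}",
                library_strategy=rng.choice(LIBRARY_STRATEGIES),
                library_source=rng.choice(LIBRARY_SOURCES),
                library_selection=rng.choice(LIBRARY_SELECTIONS),
                library_layout=rng.choice(("SINGLE", "PAIRED")),
                spot_length=rng.choice((36, 50, 76, 100)),
                platform=platform,
                instrument_model=model,
                experiment_attribute=_attrs(rng, spec),
                submission_accession=sub_acc,
            ))
            for _ in range(rng.randint(*spec.runs_per_experiment)):
                run_acc = minter.mint("run")
                spots = rng.randint(10_000, 50_000_000)
                records["run"].append(RunRecord(
                    run_accession=run_acc,
                    run_alias=f"run_{run_acc}",
                    run_date=_date(rng),
                    updated_date=_date(rng),
                    spots=spots,
                    bases=spots * rng.choice((36, 50, 76, 100)),
                    run_center=rng.choice(("NCI", "WUGSC", "BI", "KUGSPS")),
                    experiment_accession=exp_acc,
                    run_attribute=_attrs(rng, spec),
                    submission_accession=sub_acc,
                ))

    for kind, field_name, phrase in spec.planted_phrases:
        pool = records[kind]
        if not pool:
            raise ValueError(
                f"cannot plant phrase into {kind}: no {kind} records generated")
        target = rng.choice(pool)
        current = getattr(target, field_name)
        setattr(target, field_name,
                f"{current} {phrase}" if current else phrase)

    for record in spec.planted_records:
        records[record_kind(record)].append(record)
    return records


def generate(spec: SynthSpec) -> Dict[str, str]:
    """Generate one XML object-set document per entity kind."""
    records = generate_records(spec)
    return {kind: write_object_set(records[kind], kind=kind)
            for kind in sra_xml.KINDS}


def build_store(spec: SynthSpec, path=":memory:") -> metastore.MetaStore:
    """Generate, serialize, re-parse and ingest a full fixture store.

    Runs the complete pipeline (records -> XML -> parse -> load ->
    denormalize) so the resulting store is exactly what real ingestion would
    produce.
    """
    documents = generate(spec)
    store = metastore.MetaStore.create(path)
    for kind in sra_xml.KINDS:
        store.load_records(sra_xml.parse_object_set(documents[kind], kind))
    store.build_denormalized()
    return store


# ---------------------------------------------------------------------------
# the worked-example fixture

#: (run_alias, run_accession, run_date, updated_date, spots, run_center)
EXAMPLE_RUNS = (
    ("HMEC_2",        "DRR000109", "2008-12-22", "2012-06-23", 19300723, "KUGSPS"),
    ("MDAMB231_2",    "DRR000103", "2008-12-22", "2012-06-23", 6447854,  "KUGSPS"),
    ("MCF7_3",        "DRR000110", "2008-12-22", "2012-06-23", 5396205,  "KUGSPS"),
    ("T47D_I",        "DRR000106", "2008-12-22", "2012-06-23", 6272361,  "KUGSPS"),
    ("MCF7_1_paired", "DRR000093", "2008-12-22", "2012-09-06", 6141309,  "KUGSPS"),
    ("MDAMB231_1",    "DRR000095", "2008-12-22", "2012-09-06", 6110876,  "KUGSPS"),
)


def paper_example_records() -> Dict[str, list]:
    """One DDBJ breast-cancer transcriptome study with six known runs.

    A single study whose abstract contains the exact phrase "breast cancer",
    one sample, and one experiment per run (paired layout where the run alias
    says so).  The run rows carry fixed aliases, accessions, dates, spot
    counts and run centers, so searches and joins have known answers.
    """
    sub = SubmissionRecord(submission_accession="DRA000001",
                           submission_alias="KUGSPS_sub1",
                           center_name="KUGSPS",
                           submission_date="2008-12-22")
    study = StudyRecord(
        study_accession="DRP000001",
        study_alias="breast_cell_lines",
        study_title="Transcriptome analysis of human breast cancer cell lines",
        study_type="Transcriptome Analysis",
        study_abstract=("Deep sequencing of transcriptomes from human breast "
                        "cancer cell lines and normal mammary epithelial cells."),
        center_name="KUGSPS",
        submission_accession="DRA000001",
    )
    sample = SampleRecord(sample_accession="DRS000001",
                          sample_alias="breast_cell_line_pool",
                          taxon_id=9606,
                          scientific_name="Homo sapiens",
                          description="Breast cancer and normal mammary cell lines",
                          submission_accession="DRA000001")
    experiments, runs = [], []
    for i, (alias, acc, run_date, updated, spots, center) in enumerate(EXAMPLE_RUNS, 1):
        exp_acc = f"DRX{i:06d}"
        layout = "PAIRED" if "paired" in alias else "SINGLE"
        experiments.append(ExperimentRecord(
            experiment_accession=exp_acc,
            experiment_alias=f"exp_{alias}",
            title=f"Transcriptome sequencing of {alias.rsplit('_', 1)[0]}",
            study_accession="DRP000001",
            sample_accession="DRS000001",
            library_strategy="RNA-Seq",
            library_source="TRANSCRIPTOMIC",
            library_selection="cDNA",
            library_layout=layout,
            platform="ILLUMINA",
            instrument_model="Illumina Genome Analyzer II",
            submission_accession="DRA000001",
        ))
        runs.append(RunRecord(
            run_accession=acc,
            run_alias=alias,
            run_date=run_date,
            updated_date=updated,
            spots=spots,
            bases=spots * 36,
            run_center=center,
            experiment_accession=exp_acc,
            submission_accession="DRA000001",
        ))
    return {"submission": [sub], "study": [study], "sample": [sample],
            "experiment": experiments, "run": runs}


def paper_example_fixture(path=":memory:") -> metastore.MetaStore:
    """Build the worked-example store through the full ingestion pipeline."""
    records = paper_example_records()
    store = metastore.MetaStore.create(path)
    for kind in sra_xml.KINDS:
        xml = write_object_set(records[kind], kind=kind)
        store.load_records(sra_xml.parse_object_set(xml, kind))
    store.build_denormalized()
    return store
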