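"""Locate run-level sequence files on the public mirrors.

Runs live at predictable paths: EBI ENA hosts gzipped fastq under
``vol1/fastq/`` keyed by the first six characters of the run accession (with
a zero-padded numeric subdirectory for accessions longer than nine
characters), and NCBI hosts SRA containers in a ``ByRun`` hierarchy.  Path
construction is a pure function of the accession, so file lists can be built
with no network traffic; probing (size/date) is a separate, optional step
against an injectable endpoint.
"""

from __future__ import annotations

import time
import urllib.error
import urllib.request
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

from .errors import FetchError
from .metastore import MetaStore
from .search import convert_accessions
from .sra_xml import ACCESSION_PATTERNS

DEFAULT_ENA_HOST = "ftp.sra.ebi.ac.uk/vol1/fastq"
DEFAULT_NCBI_TEMPLATE = ("ftp-trace.ncbi.nih.gov/sra/sra-instant/reads/ByRun/"
                         "{sra_type}/{acc3}/{acc6}/{acc}/{fname}")
DEFAULT_TIMEOUT = 30.0


@dataclass
class FileInfo:
    """One remote sequence file and the accession lineage that owns it."""
    run_accession: Optional[str]
    experiment_accession: Optional[str]
    study_accession: Optional[str]
    sample_accession: Optional[str]
    submission_accession: Optional[str]
    file_name: str
    file_url: str
    size_bytes: Optional[int] = None
    date: Optional[str] = None
    source: str = "ena"
    protocol: str = "https"


def _ena_run_dir(run_accession: str) -> str:
    if len(run_accession) == 9:
        return f"{run_accession[:6]}/{run_accession}"
    return f"{run_accession[:6]}/{run_accession[9:].zfill(3)}/{run_accession}"


def ena_fastq_urls(run_accession: str, layout: str = "single", *,
                   base: Optional[str] = None, protocol: str = "https") -> List[str]:
    """URLs of the fastq.gz files ENA would host for one run.

    Pure path construction — no network access.  ``layout`` "single" yields
    ``{acc}.fastq.gz``; "paired" yields ``{acc}_1.fastq.gz`` and
    ``{acc}_2.fastq.gz``.
    """
    if not ACCESSION_PATTERNS["run"].match(run_accession or ""):
        raise ValueError(
            f"{run_accession!r} is not a run accession; convert other accession "
            "kinds (study/experiment/sample/submission) to runs first")
    if layout not in ("single", "paired"):
        raise ValueError(f"layout must be 'single' or 'paired', got {layout!r}")
    base = (base or DEFAULT_ENA_HOST).rstrip("/")
    prefix = f"{protocol}://{base}/{_ena_run_dir(run_accession)}"
    if layout == "single":
        return [f"{prefix}/{run_accession}.fastq.gz"]
    return [f"{prefix}/{run_accession}_1.fastq.gz",
            f"{prefix}/{run_accession}_2.fastq.gz"]


def ncbi_sra_url(run_accession: str, sra_type: str = "sra", *,
                 template: Optional[str] = None, protocol: str = "https") -> str:
    """URL of the SRA container for one run on the NCBI ByRun hierarchy."""
    if not ACCESSION_PATTERNS["run"].match(run_accession or ""):
        raise ValueError(f"{run_accession!r} is not a run accession")
    if sra_type not in ("sra", "litesra"):
        raise ValueError(f"sra_type must be 'sra' or 'litesra', got {sra_type!r}")
    fname = (f"{run_accession}.lite.sra" if sra_type == "litesra"
             else f"{run_accession}.sra")
    path = (template or DEFAULT_NCBI_TEMPLATE).format(
        sra_type=sra_type, acc3=run_accession[:3], acc6=run_accession[:6],
        acc=run_accession, fname=fname)
    return f"{protocol}://{path}"


def _layout_of(store: MetaStore, experiment_accession: Optional[str]) -> str:
    if experiment_accession is None:
        return "single"
    row = store.conn.execute(
        "SELECT library_layout FROM experiment WHERE experiment_accession = ?",
        (experiment_accession,)).fetchone()
    return "paired" if row and row[0] and row[0].upper() == "PAIRED" else "single"


def list_sra_files(store: MetaStore, accessions: Sequence[str],
                   file_type: str = "fastq", src_type: str = "ftp", *,
                   ena_base: Optional[str] = None,
                   ncbi_template: Optional[str] = None) -> List[FileInfo]:
    """Expected remote files for a set of accessions — no network round trips.

    Accessions of any kind are first resolved to runs through the store's
    entity graph.  Sizes and dates are left null; use :func:`get_fastq_info`
    or :func:`get_sra_info` to probe the server.
    """
    if file_type not in ("fastq", "sra", "litesra"):
        raise ValueError(f"file_type must be fastq/sra/litesra, got {file_type!r}")
    if src_type == "fasp":
        raise NotImplementedError(
            "the fasp (aspera) protocol requires third-party software and is "
            "not implemented; use src_type='ftp'")
    if src_type not in ("ftp", "http", "https"):
        raise ValueError(f"src_type must be 'ftp', 'http', 'https' or 'fasp', "
                         f"got {src_type!r}")
    lineage = convert_accessions(store, list(accessions)) if accessions else None
    infos: List[FileInfo] = []
    if lineage is None:
        return infos
    seen_runs = set()
    for row in lineage.itertuples(index=False):
        run = row.run
        if run is None or run in seen_runs:
            continue
        seen_runs.add(run)
        common = dict(run_accession=run, experiment_accession=row.experiment,
                      study_accession=row.study, sample_accession=row.sample,
                      submission_accession=row.submission)
        if file_type == "fastq":
            layout = _layout_of(store, row.experiment)
            urls = ena_fastq_urls(run, layout, base=ena_base, protocol=src_type)
            source = "ena"
        else:
            urls = [ncbi_sra_url(run, file_type, template=ncbi_template,
                                 protocol=src_type)]
            source = "ncbi"
        for url in urls:
            infos.append(FileInfo(**common, file_name=url.rsplit("/", 1)[1],
                                  file_url=url, source=source, protocol=src_type))
    return infos


def probe_url(url: str, *, retries: int = 3, retry_wait: float = 0.5,
              timeout: float = DEFAULT_TIMEOUT):
    """HEAD a URL; returns (size_bytes, last_modified) or None if absent (404).

    Transient network failures are retried ``retries`` times, then raised as
    :class:`FetchError`.
    """
    last_exc = None
    for attempt in range(retries):
        try:
            req = urllib.request.Request(url, method="HEAD")
            with urllib.request.urlopen(req, timeout=timeout) as resp:
                length = resp.headers.get("Content-Length")
                return (int(length) if length is not None else None,
                        resp.headers.get("Last-Modified"))
        except urllib.error.HTTPError as exc:
            if exc.code in (404, 410):
                return None
            last_exc = exc
        except (urllib.error.URLError, TimeoutError, OSError) as exc:
            last_exc = exc
        if attempt + 1 < retries:
            time.sleep(retry_wait)
    raise FetchError(f"failed to probe {url} after {retries} attempts: {last_exc}")


def _probe_infos(infos: List[FileInfo], retries, retry_wait, timeout) -> List[FileInfo]:
    available = []
    for info in infos:
        result = probe_url(info.file_url, retries=retries, retry_wait=retry_wait,
                           timeout=timeout)
        if result is None:
            warnings.warn(f"{info.file_url} absent on server; dropped", stacklevel=3)
            continue
        info.size_bytes, info.date = result
        available.append(info)
    return available


def get_fastq_info(store: MetaStore, accessions: Sequence[str], *,
                   endpoint: Optional[str] = None, protocol: str = "https",
                   retries: int = 3, retry_wait: float = 0.5,
                   timeout: float = DEFAULT_TIMEOUT) -> List[FileInfo]:
    """As :func:`list_sra_files` for fastq, but probe the server for size/date.

    Files the server does not host are dropped with a warning, so the result
    is always a subset of the unprobed listing.  ``endpoint`` overrides the
    ENA base (useful for mirrors and tests).
    """
    infos = list_sra_files(store, accessions, file_type="fastq",
                           src_type=protocol, ena_base=endpoint)
    return _probe_infos(infos, retries, retry_wait, timeout)


def get_sra_info(store: MetaStore, accessions: Sequence[str],
                 sra_type: str = "sra", *, endpoint: Optional[str] = None,
                 protocol: str = "https", retries: int = 3,
                 retry_wait: float = 0.5,
                 timeout: float = DEFAULT_TIMEOUT) -> List[FileInfo]:
    """SRA-container file information from the NCBI-style hierarchy, probed.

    ``endpoint`` overrides the path template (any string with ``{sra_type}``,
    ``{acc3}``, ``{acc6}``, ``{acc}``, ``{fname}`` placeholders).
    """
    infos = list_sra_files(store, accessions, file_type=sra_type,
                           src_type=protocol, ncbi_template=endpoint)
    return _probe_infos(infos, retries, retry_wait, timeout)
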