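"""Bulk download of located sequence files.

Downloads are streamed, resumable (HTTP range requests when the server
supports them), and verified by length against the server-reported size.
A file already present with the right size is skipped unless ``overwrite``
is set, so repeated invocations are idempotent.  Checksums are not used:
the public SRA-era endpoints do not expose them uniformly, so a byte-length
check is the strongest uniform verification available.
"""

from __future__ import annotations

import os
import shutil
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from tqdm import tqdm

from .errors import FetchError
from .filelocator import DEFAULT_TIMEOUT, FileInfo, probe_url

_CHUNK = 1 << 16


@dataclass
class DownloadReport:
    requested: int = 0
    completed: int = 0
    skipped: int = 0
    failed: List[Tuple[str, str]] = field(default_factory=list)
    dest_dir: Optional[str] = None

    def ok(self) -> bool:
        return not self.failed


def _server_size(info: FileInfo, timeout) -> Optional[int]:
    if info.size_bytes is not None:
        return info.size_bytes
    probed = probe_url(info.file_url, retries=1, timeout=timeout)
    return probed[0] if probed else None


def _download_one(info: FileInfo, dest: str, server_size: Optional[int], timeout):
    partial = os.path.exists(dest) and (
        server_size is None or os.path.getsize(dest) < server_size)
    offset = os.path.getsize(dest) if partial else 0
    headers = {"Range": f"bytes={offset}-"} if offset else {}
    req = urllib.request.Request(info.file_url, headers=headers)
    with urllib.request.urlopen(req, timeout=timeout) as resp:
        resumed = resp.status == 206
        mode = "ab" if resumed else "wb"
        with open(dest, mode) as fh:
            shutil.copyfileobj(resp, fh, _CHUNK)
    if server_size is not None and os.path.getsize(dest) != server_size:
        raise IOError(
            f"length mismatch for {info.file_name}: "
            f"got {os.path.getsize(dest)}, server reports {server_size}")


def get_files(file_infos: Sequence[FileInfo], dest_dir, overwrite: bool = False,
              *, progress: bool = False,
              timeout: float = DEFAULT_TIMEOUT) -> DownloadReport:
    """Download every located file into ``dest_dir``.

    Existing files whose size matches the server's are skipped (unless
    ``overwrite``); partial files are resumed when the server honours range
    requests.  Per-file network failures are recorded in ``report.failed``
    and the run continues.  The report always satisfies
    ``requested == completed + skipped + len(failed)``.
    """
    file_infos = list(file_infos)
    os.makedirs(dest_dir, exist_ok=True)
    report = DownloadReport(requested=len(file_infos), dest_dir=str(dest_dir))
    iterator = tqdm(file_infos, unit="file", disable=not progress)
    for info in iterator:
        dest = os.path.join(dest_dir, info.file_name)
        try:
            server_size = _server_size(info, timeout)
            if (not overwrite and server_size is not None
                    and os.path.exists(dest)
                    and os.path.getsize(dest) == server_size):
                report.skipped += 1
                continue
            if overwrite and os.path.exists(dest):
                os.remove(dest)
            _download_one(info, dest, server_size, timeout)
            report.completed += 1
        except (OSError, FetchError) as exc:
            report.failed.append((info.file_name, str(exc)))
            if isinstance(exc, OSError) and "No space left" in str(exc):
                raise  # disk full: abort, report reflects progress so far
    return report
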