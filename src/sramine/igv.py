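"""Remote-control a running IGV genome browser over its TCP command port.

IGV listens on a plain-text socket (port 60151 by default): each command is
a single newline-terminated line and IGV answers with one line, ``OK`` on
success.  This module wraps that protocol — one in-flight command at a time,
every command awaiting its acknowledgement — plus helpers to write IGV XML
session files and to launch IGV itself.  Nothing here touches the metadata
store; track files (BAM/BED/...) are passed as opaque paths.
"""

from __future__ import annotations

import re
import shutil
import socket
import subprocess
from typing import List, Optional, Sequence, Tuple

from lxml import etree

from .errors import FeatureUnavailableError, IGVError

DEFAULT_PORT = 60151

_LOCUS_RE = re.compile(r"^([A-Za-z0-9_.]+):(\d+)-(\d+)$")


def validate_locus(locus: str) -> None:
    """Validate a chr:start-end locus (1-based, inclusive) before sending."""
    m = _LOCUS_RE.match(locus or "")
    if not m:
        raise ValueError(f"malformed locus {locus!r}; expected chr:start-end")
    start, end = int(m.group(2)), int(m.group(3))
    if start < 1:
        raise ValueError(f"locus start must be >= 1 (1-based): {locus!r}")
    if start > end:
        raise ValueError(f"locus start exceeds end: {locus!r}")


class IGVConnection:
    """Live socket session to an IGV instance."""

    def __init__(self, host: str = "127.0.0.1", port: int = DEFAULT_PORT,
                 timeout: float = 60.0):
        self.host = host
        self.port = port
        self.timeout = timeout
        try:
            self._sock = socket.create_connection((host, port), timeout=timeout)
        except OSError as exc:
            raise IGVError(f"cannot connect to IGV at {host}:{port}: {exc}") from exc
        self._reader = self._sock.makefile("r", encoding="utf-8", newline="\n")
        self.open = True

    def close(self):
        if self.open:
            self._reader.close()
            self._sock.close()
            self.open = False

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def send(self, command: str) -> str:
        """Send one command line and return IGV's one-line response verbatim."""
        if not self.open:
            raise IGVError("connection is closed")
        try:
            self._sock.sendall(command.encode("utf-8") + b"\n")
            response = self._reader.readline()
        except OSError as exc:
            raise IGVError(f"socket error during {command!r}: {exc}") from exc
        if response == "":
            raise IGVError(f"connection closed by IGV during {command!r}")
        return response.rstrip("\n")

    def _command(self, command: str) -> str:
        response = self.send(command)
        if response != "OK":
            raise IGVError(f"IGV rejected {command!r}: {response}")
        return response


def connect(host: str = "127.0.0.1", port: int = DEFAULT_PORT,
            timeout: float = 60.0) -> IGVConnection:
    return IGVConnection(host, port, timeout)


def send(conn: IGVConnection, command: str) -> str:
    return conn.send(command)


def genome(conn: IGVConnection, name: str) -> None:
    """Set the reference genome, e.g. ``genome(conn, "hg18")``."""
    conn._command(f"genome {name}")


def goto(conn: IGVConnection, locus: str) -> None:
    """Move the browser view, e.g. ``goto(conn, "chr1:1-1000")``."""
    validate_locus(locus)
    conn._command(f"goto {locus}")


def load(conn: IGVConnection, paths: Sequence[str]) -> None:
    """Load one or more track files/URLs, one command per path."""
    if isinstance(paths, str):
        paths = [paths]
    for path in paths:
        conn._command(f"load {path}")


def clear(conn: IGVConnection) -> None:
    conn._command("clear")


def collapse(conn: IGVConnection, track: Optional[str] = None) -> None:
    conn._command(f"collapse {track}" if track else "collapse")


def sort_track(conn: IGVConnection, option: str) -> None:
    conn._command(f"sort {option}")


def snapshot(conn: IGVConnection, file_path: str) -> None:
    conn._command(f"snapshot {file_path}")


def new_session(conn: IGVConnection) -> None:
    conn._command("new")


def start_igv(memory_mb: int, launcher: Optional[str] = None) -> subprocess.Popen:
    """Launch IGV with the given maximum heap, returning the process handle.

    Requires an IGV launcher on PATH (or passed explicitly); absent launcher
    raises :class:`FeatureUnavailableError` rather than crashing.
    """
    if memory_mb <= 0:
        raise ValueError(f"memory_mb must be positive, got {memory_mb}")
    launcher = launcher or shutil.which("igv")
    if launcher is None or shutil.which(launcher) is None:
        raise FeatureUnavailableError(
            "no IGV launcher found on PATH; install IGV or pass launcher=")
    return subprocess.Popen([launcher, f"-Xmx{memory_mb}m"])


def write_session(file_path: str, genome_name: str,
                  track_paths: Sequence[str]) -> str:
    """Write an IGV XML session file referencing a genome and track paths."""
    track_paths = list(track_paths)
    if not track_paths:
        raise ValueError("track_paths must name at least one track")
    root = etree.Element("Session", genome=genome_name, version="8")
    resources = etree.SubElement(root, "Resources")
    for path in track_paths:
        etree.SubElement(resources, "Resource", path=str(path))
    data = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    with open(file_path, "wb") as fh:
        fh.write(data)
    return file_path


def read_session(file_path: str) -> Tuple[str, List[str]]:
    """Parse a session file back to (genome, track paths)."""
    root = etree.parse(file_path).getroot()
    return (root.get("genome"),
            [r.get("path") for r in root.findall("Resources/Resource")])
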