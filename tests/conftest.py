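import functools
import http.server
import os
import socket
import socketserver
import threading

import pytest
from hypothesis import settings

from sramine import synth

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def paper_store():
    """The worked-example store: one breast-cancer study with six known runs."""
    return synth.paper_example_fixture()


@pytest.fixture()
def small_store():
    return synth.build_store(synth.SynthSpec(seed=11, n_studies=2))


class _RangeHandler(http.server.SimpleHTTPRequestHandler):
    """File server with HEAD, GET and single-range GET support."""

    def log_message(self, *args):
        pass

    def send_head(self):
        path = self.translate_path(self.path)
        if os.path.isfile(path):
            range_header = self.headers.get("Range")
            if range_header and range_header.startswith("bytes="):
                start = int(range_header[6:].split("-")[0])
                size = os.path.getsize(path)
                if start < size:
                    fh = open(path, "rb")
                    fh.seek(start)
                    self.send_response(206)
                    self.send_header("Content-Type", "application/octet-stream")
                    self.send_header("Content-Range", f"bytes {start}-{size-1}/{size}")
                    self.send_header("Content-Length", str(size - start))
                    self.end_headers()
                    return fh
        return super().send_head()


@pytest.fixture()
def http_fileserver(tmp_path):
    """Serve a temp directory over HTTP; yields (base_url, root_dir)."""
    root = tmp_path / "www"
    root.mkdir()
    handler = functools.partial(_RangeHandler, directory=str(root))
    with socketserver.TCPServer(("127.0.0.1", 0), handler) as httpd:
        port = httpd.server_address[1]
        thread = threading.Thread(target=httpd.serve_forever, daemon=True)
        thread.start()
        try:
            yield f"http://127.0.0.1:{port}", root
        finally:
            httpd.shutdown()
            thread.join(timeout=5)


class MockIGVServer:
    """Accepts IGV-protocol connections, answers per script, records commands."""

    def __init__(self, responses=None):
        self.received = []
        self.responses = responses or {}
        self._sock = socket.socket()
        self._sock.bind(("127.0.0.1", 0))
        self._sock.listen(1)
        self.port = self._sock.getsockname()[1]
        self._thread = threading.Thread(target=self._serve, daemon=True)
        self._thread.start()

    def _serve(self):
        try:
            conn, _ = self._sock.accept()
        except OSError:
            return
        with conn, conn.makefile("rw", encoding="utf-8", newline="\n") as fh:
            for line in fh:
                command = line.rstrip("\n")
                self.received.append(command)
                fh.write(self.responses.get(command, "OK") + "\n")
                fh.flush()

    def close(self):
        self._sock.close()

    @property
    def transcript(self):
        return "".join(c + "\n" for c in self.received)


@pytest.fixture()
def igv_server():
    server = MockIGVServer()
    yield server
    server.close()
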