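"""Line-oriented TCP server exposing live modification frequencies.

While processing continues, third-party applications (for instance
adaptive-sampling controllers deciding whether a region has accumulated
enough high-confidence calls) can query the current table over a plain
socket.  One request per line; responses are zero or more TSV record lines
followed by a terminator line ``END``; errors are a single ``ERR <message>``
line.

Commands::

    GET_CONTIG <contig>                      all rows on a contig
    GET_RANGE <contig> <start> <end>         rows with start <= pos < end
    GET_COVERED <contig> <start> <end> <n>   count of sites with n_called >= n
    HELP                                     this summary

Query handling acquires the table's writer lock, so a response is always a
consistent snapshot: a client never observes a file's counts half-applied.
"""

from __future__ import annotations

import logging
import socketserver
import threading

from .freqstore import FrequencyTable
from .writers import format_tsv_row

logger = logging.getLogger(__name__)

__all__ = ["ModServer", "HELP_TEXT"]

HELP_TEXT = [
    "GET_CONTIG <contig>",
    "GET_RANGE <contig> <start> <end>",
    "GET_COVERED <contig> <start> <end> <min_called>",
    "HELP",
]


class _Handler(socketserver.StreamRequestHandler):
    def handle(self) -> None:
        server: "ModServer" = self.server.modserver  # type: ignore[attr-defined]
        while True:
            line = self.rfile.readline()
            if not line:
                return
            try:
                request = line.decode("utf-8", errors="replace").strip()
            except Exception:
                self._send(["ERR undecodable request"])
                continue
            if not request:
                continue
            self._send(server.respond(request))

    def _send(self, lines: list[str]) -> None:
        payload = "".join(line + "\n" for line in lines)
        self.wfile.write(payload.encode("utf-8"))
        self.wfile.flush()


class _TCPServer(socketserver.ThreadingTCPServer):
    allow_reuse_address = True
    daemon_threads = True


class ModServer:
    """Threaded TCP front-end over a :class:`FrequencyTable`.

    ``port=0`` binds an ephemeral port (useful for tests); the bound port
    is available as :attr:`port` after :meth:`start`.
    """

    def __init__(
        self,
        table: FrequencyTable,
        host: str = "127.0.0.1",
        port: int = 8080,
        min_called: int = 1,
    ) -> None:
        self.table = table
        self.min_called = min_called
        try:
            self._server = _TCPServer((host, port), _Handler)
        except OSError as exc:
            raise OSError(f"cannot bind {host}:{port}: {exc}") from exc
        self._server.modserver = self  # type: ignore[attr-defined]
        self._thread: threading.Thread | None = None

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    def start(self) -> None:
        self._thread = threading.Thread(
            target=self._server.serve_forever, name="modfreq-server", daemon=True
        )
        self._thread.start()
        logger.info("server listening on port %d", self.port)

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    # -- request dispatch ---------------------------------------------------

    def respond(self, request: str) -> list[str]:
        parts = request.split()
        cmd = parts[0].upper()
        try:
            if cmd == "GET_CONTIG" and len(parts) == 2:
                return self._rows(parts[1]) + ["END"]
            if cmd == "GET_RANGE" and len(parts) == 4:
                start, end = self._parse_range(parts[2], parts[3])
                return self._rows(parts[1], start, end) + ["END"]
            if cmd == "GET_COVERED" and len(parts) == 5:
                start, end = self._parse_range(parts[2], parts[3])
                min_called = int(parts[4])
                if min_called < 0:
                    raise ValueError("min_called must be >= 0")
                return [
                    str(self.high_confidence_coverage(parts[1], start, end, min_called)),
                    "END",
                ]
            if cmd == "HELP":
                return HELP_TEXT + ["END"]
        except ValueError as exc:
            return [f"ERR {exc}"]
        return ["ERR unknown command"]

    @staticmethod
    def _parse_range(start_s: str, end_s: str) -> tuple[int, int]:
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(f"malformed range {start_s} {end_s}") from None
        if start >= end:
            raise ValueError(f"empty range: require start < end, got {start} {end}")
        return start, end

    def _rows(
        self, contig: str, start: int | None = None, end: int | None = None
    ) -> list[str]:
        floor = max(self.min_called, 1)
        out = []
        for key, stats in self.table.sorted_items():
            if key.contig != contig or stats.n_called < floor:
                continue
            if start is not None and not start <= key.ref_pos < end:  # type: ignore[operator]
                continue
            out.append(format_tsv_row(key, stats))
        return out

    def high_confidence_coverage(
        self, contig: str, start: int, end: int, min_called: int
    ) -> int:
        """Sites in [start, end) whose confident coverage meets min_called."""
        with self.table.lock:
            return sum(
                1
                for key, stats in self.table.items()
                if key.contig == contig
                and start <= key.ref_pos < end
                and stats.n_called >= min_called
            )
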