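"""Directory monitoring for newly completed sequencing batch files.

Sequencers write batch files (POD5, or modBAM when live modification
calling is enabled) into nested run directories as the experiment
progresses.  The watcher emits the absolute path of each matching file
exactly once, only after the file has stopped growing (its size is
unchanged across a stability interval), and never re-emits paths recorded
in a processed-file log from a previous, resumed run.

The implementation polls at a configurable interval.  The emitted-once /
complete-only / dedupe contract is what callers and tests rely on, not the
notification mechanism.
"""

from __future__ import annotations

import logging
import os
import shlex
import subprocess
import threading
import time
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = ["DirectoryWatcher", "WatcherError", "run_pipeline_hook"]


class WatcherError(RuntimeError):
    pass


class DirectoryWatcher:
    """Emit stabilized matching files from a directory tree, exactly once.

    Parameters
    ----------
    directory:
        Root to watch (recursively; sequencers nest batch subdirectories).
    extension:
        Filename suffix filter, e.g. ``".bam"`` or ``".pod5"``.
    processed:
        Paths (from a resume log) that must never be emitted again.
    stability_interval:
        Seconds a file's size must remain unchanged before it is
        considered complete. Default 2 s.
    poll_interval:
        Seconds between directory scans.
    """

    def __init__(
        self,
        directory: str | os.PathLike,
        extension: str = ".bam",
        processed: Iterable[str] = (),
        stability_interval: float = 2.0,
        poll_interval: float = 0.5,
    ) -> None:
        self.directory = os.path.abspath(str(directory))
        self.extension = extension
        self.stability_interval = stability_interval
        self.poll_interval = poll_interval
        self._emitted: set[str] = {os.path.abspath(p) for p in processed}

    def _scan(self) -> list[str]:
        found = []
        for root, _dirs, files in os.walk(self.directory):
            for name in files:
                if name.endswith(self.extension):
                    found.append(os.path.join(root, name))
        return found

    def watch(self, stop_event: threading.Event | None = None) -> Iterator[str]:
        """Yield absolute paths of complete, unseen matching files.

        Runs until ``stop_event`` is set.  Raises :class:`WatcherError` if
        the watched directory disappears.
        """
        if not os.path.isdir(self.directory):
            raise WatcherError(f"watch directory does not exist: {self.directory}")
        # (size, first time observed at that size)
        pending: dict[str, tuple[int, float]] = {}
        while stop_event is None or not stop_event.is_set():
            if not os.path.isdir(self.directory):
                raise WatcherError(f"watch directory vanished: {self.directory}")
            now = time.monotonic()
            for path in self._scan():
                if path in self._emitted:
                    continue
                try:
                    size = os.path.getsize(path)
                except OSError:
                    logger.warning("file vanished before emission: %s", path)
                    pending.pop(path, None)
                    continue
                prev = pending.get(path)
                if prev is None or prev[0] != size:
                    pending[path] = (size, now)
                    continue
                if now - prev[1] >= self.stability_interval:
                    if not os.path.exists(path):
                        logger.warning("file vanished before emission: %s", path)
                        pending.pop(path, None)
                        continue
                    self._emitted.add(path)
                    pending.pop(path, None)
                    yield path
            if stop_event is not None:
                if stop_event.wait(self.poll_interval):
                    break
            else:
                time.sleep(self.poll_interval)


def run_pipeline_hook(cmd_template: str, input_path: str) -> str:
    """Run the user-supplied external pipeline on a raw-signal file.

    ``{path}`` in the template is replaced with the triggering file.  The
    command must print the resulting modBAM path as its last non-empty
    stdout line; that path is returned.  The pipeline's internals
    (conversion, basecalling, alignment) are entirely the command's
    business.
    """
    cmd = cmd_template.replace("{path}", shlex.quote(input_path))
    proc = subprocess.run(
        cmd, shell=True, capture_output=True, text=True, check=True
    )
    lines = [line for line in proc.stdout.splitlines() if line.strip()]
    if not lines:
        raise WatcherError(
            f"pipeline command produced no output path for {input_path}"
        )
    return lines[-1].strip()
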