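"""Delimited text output for time-series model data."""

from __future__ import annotations

from .errors import StateError


class DelimitedWriter:
    """Line-oriented writer of delimiter-separated values.

    Thin wrapper over a text file handle: ``write`` appends raw text,
    ``write_row`` joins values with the delimiter and appends a newline.
    Closed writers reject writes; content is flushed on close.
    """

    def __init__(self, path, mode: str = "w", delimiter: str = ","):
        if mode not in ("w", "a"):
            raise ValueError("mode must be 'w' or 'a'")
        self.path = path
        self.delimiter = delimiter
        self._fh = open(path, mode)

    @property
    def closed(self) -> bool:
        return self._fh is None

    def write(self, text: str) -> None:
        """Append raw text exactly as given."""
        if self._fh is None:
            raise StateError("write to a closed DelimitedWriter")
        self._fh.write(text)

    def write_row(self, values) -> None:
        """Append one delimited row followed by a newline."""
        self.write(self.delimiter.join(str(v) for v in values) + "\n")

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
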