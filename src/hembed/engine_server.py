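"""Standalone engine server process.

Reads length-prefixed protocol frames from stdin, feeds them to an
:class:`~hembed.protocol.EngineServer`, and writes length-prefixed replies
to stdout.  Launched by the two-process transport as

    python -m hembed.engine_server
"""

from __future__ import annotations

import struct
import sys


def main() -> int:
    from .protocol import EngineServer

    server = EngineServer()
    stdin = sys.stdin.buffer
    stdout = sys.stdout.buffer
    while True:
        head = stdin.read(8)
        if len(head) < 8:
            return 0
        (n,) = struct.unpack("<Q", head)
        frame = stdin.read(n)
        if len(frame) < n:
            return 1
        reply = server.handle_frame(frame)
        stdout.write(struct.pack("<Q", len(reply)) + reply)
        stdout.flush()
        if server.finalized:
            return 0


if __name__ == "__main__":
    sys.exit(main())
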