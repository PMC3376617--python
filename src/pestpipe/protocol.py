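"""Framed serial transmission with stop-and-wait retransmission.

Every frame is 517 bytes on the wire: a two-byte head (0x1B 0x7E), a
big-endian 16-bit sequence number, exactly 512 payload bytes, and the
end byte 0xFF.  A payload of arbitrary length is carried as a leading
length frame (4-byte big-endian total length, zero padded to 512)
followed by the data frames, the last one zero padded; sequence numbers
run consecutively from 0 and wrap at 65536.  There is no checksum in
the frame itself — error handling lives in the link discipline, where
an erroneous reply triggers a connection reset.

The link discipline is stop-and-wait with a single frame in flight:
send, await the reply; a timeout (no reply) retransmits the same frame;
an erroneous reply resets the connection and resumes from the
unacknowledged frame; a correct reply advances to the next frame.  The
:class:`ChannelModel` simulator stands in for the radio link, replying
ACK (0x06), NAK (0x15) or nothing according to seeded drop/corruption
probabilities; these reply bytes are a convention of the simulator, not
of the wire format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DeliveryError, FramingError

HEAD = b"\x1b\x7e"
END = b"\xff"
PAYLOAD_SIZE = 512
FRAME_SIZE = 2 + 2 + PAYLOAD_SIZE + 1  # 517
SEQ_MODULO = 65536

ACK = b"\x06"
NAK = b"\x15"


@dataclass(frozen=True)
class Frame:
    seq: int
    payload: bytes

    def __post_init__(self):
        if not (0 <= self.seq < SEQ_MODULO):
            raise FramingError(f"sequence number {self.seq} out of range")
        if len(self.payload) != PAYLOAD_SIZE:
            raise FramingError(
                f"payload must be exactly {PAYLOAD_SIZE} bytes, got {len(self.payload)}"
            )

    def serialize(self) -> bytes:
        return HEAD + self.seq.to_bytes(2, "big") + self.payload + END

    @classmethod
    def deserialize(cls, data: bytes) -> "Frame":
        if len(data) != FRAME_SIZE:
            raise FramingError(f"frame must be {FRAME_SIZE} bytes, got {len(data)}")
        if data[:2] != HEAD:
            raise FramingError(f"bad frame head {data[:2].hex()}")
        if data[-1:] != END:
            raise FramingError(f"bad frame end byte {data[-1:].hex()}")
        seq = int.from_bytes(data[2:4], "big")
        return cls(seq=seq, payload=data[4:-1])


def packetize(payload: bytes) -> list[Frame]:
    """Split a payload into a length frame plus zero-padded data frames."""
    if len(payload) == 0:
        raise ValueError("empty payload")
    frames = [
        Frame(seq=0, payload=len(payload).to_bytes(4, "big").ljust(PAYLOAD_SIZE, b"\x00"))
    ]
    for i in range(0, len(payload), PAYLOAD_SIZE):
        chunk = payload[i : i + PAYLOAD_SIZE].ljust(PAYLOAD_SIZE, b"\x00")
        frames.append(Frame(seq=(1 + i // PAYLOAD_SIZE) % SEQ_MODULO, payload=chunk))
    return frames


def depacketize(frames: list[Frame]) -> bytes:
    """Reassemble the payload; the exact inverse of :func:`packetize`."""
    if not frames:
        raise FramingError("no frames")
    expected = frames[0].seq
    for f in frames:
        if f.seq != expected:
            raise FramingError(
                f"sequence gap: expected seq {expected}, got seq {f.seq}"
            )
        expected = (expected + 1) % SEQ_MODULO
    length = int.from_bytes(frames[0].payload[:4], "big")
    data = b"".join(f.payload for f in frames[1:])
    if length > len(data):
        raise FramingError(
            f"length prefix {length} exceeds available data {len(data)}"
        )
    return data[:length]


@dataclass
class ChannelModel:
    """Seeded lossy-link test double.

    Each transmission independently gets no reply with probability
    ``drop_prob`` (frame or acknowledgement lost), otherwise an
    erroneous reply with probability ``corrupt_prob``, otherwise a
    correct ACK.
    """

    drop_prob: float = 0.0
    corrupt_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.drop_prob <= 1.0 and 0.0 <= self.corrupt_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        self._rng = np.random.default_rng(self.seed)

    def transmit(self, frame_bytes: bytes) -> bytes | None:
        """Returns ACK, NAK, or None (silence / timeout)."""
        if self._rng.random() < self.drop_prob:
            return None
        if self._rng.random() < self.corrupt_prob:
            return NAK
        return ACK


@dataclass(frozen=True)
class LinkConfig:
    timeout: float = 1.0  # seconds of simulated waiting per silent attempt
    max_retries_before_reset: int = 5  # consecutive timeouts before a reset
    retry_budget: int = 100  # total attempts allowed per frame

    def __post_init__(self):
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")
        if self.max_retries_before_reset < 1 or self.retry_budget < 1:
            raise ValueError("retry limits must be >= 1")


@dataclass
class TransmissionLog:
    """Every link event, in order, plus summary counters."""

    events: list[tuple] = field(default_factory=list)
    sends: int = 0
    retransmits: int = 0
    timeouts: int = 0
    naks: int = 0
    resets: int = 0
    acked: int = 0

    def record(self, kind: str, *args):
        self.events.append((kind, *args))

    def lines(self):
        for ev in self.events:
            yield " ".join(str(v) for v in ev)


def send(
    frames: list[Frame],
    channel: ChannelModel,
    cfg: LinkConfig = LinkConfig(),
) -> TransmissionLog:
    """Deliver frames over the simulated link, stop-and-wait.

    The sender never moves past an unacknowledged frame.  Exhausting
    ``retry_budget`` attempts on a single frame raises
    :class:`DeliveryError` carrying the partial log.
    """
    log = TransmissionLog()
    for frame in frames:
        wire = frame.serialize()
        attempts = 0
        consecutive_timeouts = 0
        while True:
            if attempts >= cfg.retry_budget:
                log.record("fail", frame.seq)
                raise DeliveryError(
                    f"frame seq {frame.seq} undelivered after {attempts} attempts",
                    log=log,
                )
            attempts += 1
            log.record("send", frame.seq, attempts)
            log.sends += 1
            if attempts > 1:
                log.retransmits += 1
            reply = channel.transmit(wire)
            if reply == ACK:
                log.record("ack", frame.seq)
                log.acked += 1
                break
            if reply is None:
                log.record("timeout", frame.seq)
                log.timeouts += 1
                consecutive_timeouts += 1
                if consecutive_timeouts >= cfg.max_retries_before_reset:
                    log.record("reset", frame.seq)
                    log.resets += 1
                    consecutive_timeouts = 0
                continue
            # erroneous reply: reset the connection, resume same frame
            log.record("nak", frame.seq)
            log.naks += 1
            log.record("reset", frame.seq)
            log.resets += 1
            consecutive_timeouts = 0
    return log
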