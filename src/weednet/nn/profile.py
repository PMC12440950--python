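"""Multiply-accumulate counting for forward passes.

Activated as a context manager; the convolution and matmul kernels
report their MAC counts here. FLOPs are reported as 2x MACs, the
convention used by the common detector profilers.
"""

from __future__ import annotations

import contextlib
from collections import defaultdict

_active = False
_macs = 0
_by_tag = defaultdict(int)
_tag_stack: list[str] = []


def add_macs(n: int) -> None:
    global _macs
    if _active:
        _macs += int(n)
        if _tag_stack:
            _by_tag[_tag_stack[-1]] += int(n)


@contextlib.contextmanager
def tag(name: str):
    """Attribute MACs recorded inside the block to `name`."""
    _tag_stack.append(name)
    try:
        yield
    finally:
        _tag_stack.pop()


@contextlib.contextmanager
def count_macs():
    """Yields a dict populated with 'macs' and per-tag counts on exit."""
    global _active, _macs
    prev, prev_macs = _active, _macs
    _active, _macs = True, 0
    _by_tag.clear()
    result: dict = {}
    try:
        yield result
    finally:
        result["macs"] = _macs
        result["by_module"] = dict(_by_tag)
        _active, _macs = prev, prev_macs
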