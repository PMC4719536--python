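"""Toy greedy de Bruijn unitig assembler — a test fixture, not a real assembler.

Collects k-mers from both strands of the input reads and walks maximal
unambiguous paths (unique right extension whose target has a unique left
extension).  Adequate for error-free synthetic reads of low-repeat
references; used to exercise the saturation and pipeline orchestration
without an external assembler.
"""

from __future__ import annotations

from typing import Sequence

from bacpool.model import ReadPair, revcomp


def assemble_reads(reads: Sequence[str], k: int = 21, min_contig: int = 100) -> list[str]:
    kmers: set[str] = set()
    for r in reads:
        for s in (r, revcomp(r)):
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if "N" not in km:
                    kmers.add(km)

    def right_ext(node: str) -> list[str]:
        suf = node[1:]
        return [c for c in "ACGT" if suf + c in kmers]

    def left_ext(node: str) -> list[str]:
        pre = node[:-1]
        return [c for c in "ACGT" if c + pre in kmers]

    visited: set[str] = set()
    contigs: list[str] = []
    for start in kmers:
        if start in visited:
            continue
        path = [start]
        on_path = {start}
        node = start
        while True:
            ext = right_ext(node)
            if len(ext) != 1:
                break
            nxt = node[1:] + ext[0]
            if nxt in on_path or nxt in visited or len(left_ext(nxt)) != 1:
                break
            path.append(nxt)
            on_path.add(nxt)
            node = nxt
        node = start
        left_path: list[str] = []
        while True:
            ext = left_ext(node)
            if len(ext) != 1:
                break
            prv = ext[0] + node[:-1]
            if prv in on_path or prv in visited or len(right_ext(prv)) != 1:
                break
            left_path.append(prv)
            on_path.add(prv)
            node = prv
        nodes = left_path[::-1] + path
        seq = nodes[0] + "".join(n[-1] for n in nodes[1:])
        for n in nodes:
            visited.add(n)
            visited.add(revcomp(n))
        if len(seq) >= min_contig:
            contigs.append(seq)
    # canonical strand + deterministic order regardless of set iteration
    contigs = [min(c, revcomp(c)) for c in contigs]
    contigs.sort(key=lambda c: (-len(c), c))
    return contigs


def assemble_pairs(pairs: Sequence[ReadPair], k: int = 21, min_contig: int = 100) -> list[str]:
    reads: list[str] = []
    for p in pairs:
        reads.append(p.read1)
        reads.append(p.read2)
    return assemble_reads(reads, k=k, min_contig=min_contig)
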