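"""Read filtering rules and error-probability trimming.

Applies the four whole-read rejection rules (N runs, low-quality base
count, median quality, length) to a few hand-built reads, then shows the
Mott-style trimmer extracting the good core of a quality-degraded trace
at the 0.01 error-probability limit.
"""

from allelecap.formats import QualifiedRead
from allelecap.qc import FilterRules, filter_read, mott_trim

rules = FilterRules()  # reject >=3 consecutive N, >=3 bases <=Q20,
                       # median <Q20, length <150

reads = {
    "clean": QualifiedRead("clean", "ACGT" * 50, (35,) * 200),
    "n_run": QualifiedRead("n_run", "ACGT" * 25 + "NNN" + "A" * 97, (35,) * 200),
    "low_q": QualifiedRead("low_q", "ACGT" * 50, (18,) * 3 + (35,) * 197),
    "short": QualifiedRead("short", "ACGT" * 30, (35,) * 120),
}
for name, read in reads.items():
    verdict = filter_read(read, rules)
    print(f"{name:6s} keep={verdict.keep!s:5s} reasons={list(verdict.reasons)}")

# a trace whose ends are bad but whose middle is fine
quals = [4] * 20 + [40] * 300 + [6] * 30
trace = QualifiedRead("trace", "A" * 350, tuple(quals))
trimmed, start, end = mott_trim(trace, error_limit=0.01)
print(f"mott trim kept [{start}, {end}) = {len(trimmed)} of {len(trace)} bases")
# the kept segment is exactly the high-quality core: each base contributes
# (0.01 - its error probability), and the best-sum segment wins
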