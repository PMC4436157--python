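"""Frequent sequential pattern mining on a four-sequence toy database.

Shows per-sequence support counting, subsequence inclusion, and the
frequent-pattern set at a support threshold, cross-checked against the
exhaustive brute-force miner.
"""

from seqmine.mining import (
    MiningConfig,
    is_subsequence,
    mine_frequent,
    mine_frequent_bruteforce,
    relative_support,
    support,
)

sdb1 = [tuple("abcd"), tuple("bde"), tuple("acde"), tuple("adcb")]

print("inclusion <b d> in <a b c d>:", is_subsequence(("b", "d"), tuple("abcd")))
print("support(<b d>)         =", support(("b", "d"), sdb1),
      " # sequences 1 and 2 contain it")
print("relative support(<b d>) =", relative_support(("b", "d"), sdb1))

print("\nfrequent patterns at minsup=3 (pattern, support):")
for p in mine_frequent(sdb1, MiningConfig(minsup=3)):
    print("  ", " ".join(p.items), p.support)

assert mine_frequent(sdb1, MiningConfig(3)) == mine_frequent_bruteforce(
    sdb1, MiningConfig(3)
)
print("\nminer agrees with the exhaustive brute-force oracle.")
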