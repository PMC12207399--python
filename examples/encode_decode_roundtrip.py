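"""Encode a short message into symbol payloads and decode it back.

Each 8-nt symbol carries 16 bits under the default A=00, C=01, G=10, T=11
map, so a five-symbol strand stores 80 bits.
"""

from splintstore import bits_to_symbols, symbols_to_bits

message = b"Hi"
bits = "".join(format(byte, "08b") for byte in message)
bits = bits.ljust(16 * ((len(bits) + 15) // 16), "0")  # pad to a symbol block

payloads = bits_to_symbols(bits)
print(f"message {message!r} -> {len(bits)} bits -> {len(payloads)} symbol payload(s)")
for p in payloads:
    print(" ", p)

recovered = symbols_to_bits(payloads)
assert recovered == bits
print("decoded bits match the input:", recovered == bits)
print("capacity: each payload is 8 nt = 16 bits; five payloads would hold 80 bits")
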