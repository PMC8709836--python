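# Alternate (KV) rendering of the arm-E main sequence, mapped against the
# older reference order.  Its band universe differs from the revised (GV)
# listings; never validate or compare it against them.
h'agiE1 1a-3e 5a-10b 4h-3f 10c-13g C
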