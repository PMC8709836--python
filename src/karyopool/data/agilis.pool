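# Chironomus agilis banding-sequence pool.
# Arms A-F are band-mapped; arm G carries two nucleolar organisers and two
# Balbiani rings and has no published band map.
# arms: A B C D E F G
p'agiA1 1a-2c 10a-12c 3i-2h 4d-9e 2d-g 4c-a 13a-19f C
p'agiA2 1a-2c 10a-12c 3i 6a-4d 2h-3h 6b-9e 2d-g 4c-a 13a-19f C
p'agiB1 25s-q 18n-16a 22a-r 25k-23f 15g-r 21t-i 18o-21h 25p-l 22s-23e 15f-12v C
p'agiB2 25s-q 18n-16a 22ab 23c-22s 25l-p 21h-18o 21i-t 15r-g 23f-25k 22r-c 23de 15f-12v C
p'agiB3 25s-q 18n-16a 22ab 23c-22s 25l-p 21h-18o 21i-t 15r-m 24m-23f 15g-l 24n-25k 22r-c 23de 15f-12v C
p'agiC1 1a-2c 6c-f 7a-d 16a-17a 6hg 11d-15e 8a-11c 6b-2d 17b-22g C
# In the source C2 listing the stretch between 16h-a and 2c-1f is written as
# the single range 7d-6c; bands 6g-h are mapped separately in the same listing
# (token 6gh), so the fused range would cover them twice.  It is stored here
# split as 7d-a 6f-c, which restores the band-set permutation property of the
# arm.
p'agiC2 1a-e 5b-4h 16h-a 7d-a 6f-c 2c-1f 5c-6b 11c-8a 15e-11d 6gh 17a 4g-2d 17b-22g C
p'agiD1 1a-d 4a-7g 18a-d 8a-10a 13a-11a 3g-1e 10e-b 13b-14a 20d-18e 17f-14b 21a-24g C
p'agiD2 1a-d 4a-7g 18a-d 8a-10a 13a-11a 3g-1e 10e-b 13bc 16a-17f 18e-20d 14a-13d 15e-14b 21a-24g C
p'agiD3 1a-d 4a-7g 18a-d 8a-10a 13a-11a 3g-2h 19a-20d 14a-13b 10b-e 1e-2g 18g-e 17f-14b 21a-24g C
# Arm E is stored in the revised (GV) mapping; the older (KV) rendering of
# h'agiE1 lives in arm_e_kv.pool and must never be mixed with GV listings.
h'agiE1 1a-3a 4c-10b 3e-b 4b-3f 10c-13g C
p'agiE2 1a-3a 4c-10b 3e-b 4b-3f 10c-e 12g-10f 13a-g C
p'agiF1 1a-d 6e-1e 7a-10d 18c-a 11a-17d 18d-23f C
p'agiF2 1a-d 6e-b 4c-6a 2a-4b 1i-e 7a-10d 18c-a 11a-17d 18d-23f C
p'agiF3 1a-d 6e-1e 7a-10d 18c-a 11a-17d 18d-21d 22e-a 23a-f C
p'agiG1 unmapped
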