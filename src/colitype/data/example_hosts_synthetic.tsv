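host_id	species	habitat	diet
E1_0000	deer	wild	herbivorous
E1_0001	deer	wild	herbivorous
E1_0002	deer	wild	herbivorous
E2_0000	cow	domesticated	herbivorous
E2_0001	domesticated_rabbit	domesticated	herbivorous
E2_0002	sheep	domesticated	herbivorous
E3_0000	boar	wild	omnivorous
E3_0001	boar	wild	omnivorous
E3_0002	chicken	domesticated	omnivorous
E4_0000	human	human	omnivorous
E4_0001	human	human	omnivorous
E4_0002	human	human	omnivorous
E5_0000	human	human	omnivorous
E5_0001	human	human	omnivorous
E5_0002	human	human	omnivorous
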