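# Toy 18S accessibility-class map (synthetic): interval -> brightness class
# I (brightest) .. VI (dimmest).  Illustrates the file format only; real
# analyses should supply the published class map for their reference 18S.
start	end	class
1	300	II
301	600	I
601	900	IV
901	1200	III
1201	1500	VI
1501	1800	II
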