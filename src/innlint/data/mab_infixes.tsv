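# Monoclonal-antibody name infixes: source class and target/disease class.
# The target infix "tu" (tumour) carries no optional vowel and is absent from
# some printed reference tables, but established names such as trastuzumab
# (tras-tu-zu-mab) require it, so it is shipped here.
kind	base	vowel	meaning	example
source	a		rat
source	axo		rat/mouse	catumaxomab
source	e		hamster
source	i		primate
source	o		mouse	solitomab
source	u		human	namilumab
source	xi		chimeric	pagibaximab
source	xizu		chimeric/humanized	otelixizumab
source	zu		humanised	natalizumab
target	b	a	bacterial	tefibazumab
target	c	i	cardiovascular	volociximab
target	f	u	fungal
target	k	i	interleukin	lebrikizumab
target	l	i	immunomodulating	infliximab
target	n	e	neural	atinumab
target	s	o	bone	romosozumab
target	tox	a	toxin	urtoxazumab
target	tu		tumour	trastuzumab
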