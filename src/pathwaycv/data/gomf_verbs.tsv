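gomf_term	verb	template
biotin-protein ligase activity	biotinylates	catalyzes
prostaglandin-D synthase activity	isomerizes	catalyzes
protein serine/threonine kinase activity	phosphorylates	catalyzes
protein tyrosine kinase activity	phosphorylates	catalyzes
hexokinase activity	phosphorylates	catalyzes
hydrolase activity	hydrolyses	catalyzes
alpha-1,2-mannosyltransferase activity	transfers	transfers
glycylpeptide N-tetradecanoyltransferase activity	transfers	transfers
transmembrane transporter activity	transports	transports
ABC-type transporter activity	transports	transports
sodium:proton antiporter activity	exchanges	exchanges
antiporter activity	exchanges	exchanges
sialic acid:proton symporter activity	cotransports	cotransports
gamma-aminobutyric acid:sodium:chloride symporter activity	cotransports	cotransports
symporter activity	cotransports	cotransports
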